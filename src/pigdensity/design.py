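"""Data-preparation procedures for the density compilation.

Three steps precede any modelling: repeated estimates of the same area
are averaged into one record per site; island and mainland densities
are compared with a Welch (unequal-variance) two-sample t-test, after
which islands are set aside; and zero-density background records are
drawn from a planar ring 100-1000 km outside the native-range boundary,
in numbers proportional to the ring/native area ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

from .records import RECORD_COLUMNS, DataError, validate_records

__all__ = [
    "WelchResult",
    "InsufficientDataError",
    "aggregate_records",
    "compare_island_mainland",
    "welch_from_summaries",
    "sample_background",
    "read_polygon",
    "write_polygon",
]


def read_polygon(path) -> Polygon:
    """Read a polygon from a delimited text file of x<TAB>y vertex rows
    (closed ring; a repeated final vertex is tolerated)."""
    pts = pd.read_csv(path, sep="\t")
    poly = Polygon(zip(pts["x"], pts["y"]))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError(f"invalid polygon in {path}")
    return poly


def write_polygon(polygon: Polygon, path) -> None:
    xs, ys = polygon.exterior.coords.xy
    pd.DataFrame({"x": xs, "y": ys}).to_csv(path, sep="\t", index=False)


class InsufficientDataError(ValueError):
    """Raised when a group is too small for the requested test."""


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t-test: t, Welch-Satterthwaite df, two-sided p,
    and per-group mean / standard error."""

    t: float
    df: float
    p: float
    mean1: float
    se1: float
    mean2: float
    se2: float


def aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated estimates: one record per ``site_key`` with the
    arithmetic-mean density.

    Coordinates, island flag and region are taken from the group and
    must agree within it; conflicting flags raise :class:`DataError`.
    Idempotent: aggregating an already-aggregated table is a no-op.
    """
    validate_records(records)
    if records["site_key"].isna().any():
        raise DataError("site_key required for aggregation")
    out_rows = []
    for key, grp in records.groupby("site_key", sort=False):
        for col in ("is_island", "region"):
            if grp[col].nunique() > 1:
                raise DataError(f"site {key!r}: conflicting {col} within group")
        if grp["x"].nunique() > 1 or grp["y"].nunique() > 1:
            raise DataError(f"site {key!r}: conflicting coordinates within group")
        first = grp.iloc[0]
        out_rows.append(
            {
                "id": first["id"],
                "x": first["x"],
                "y": first["y"],
                "density": float(grp["density"].mean()),
                "is_island": bool(first["is_island"]),
                "region": first["region"],
                "site_key": key,
            }
        )
    return pd.DataFrame(out_rows, columns=RECORD_COLUMNS)


def compare_island_mainland(records: pd.DataFrame, log_scale: bool = False) -> WelchResult:
    """Welch t-test of island vs mainland density.

    Background records are excluded.  With ``log_scale`` the densities
    are natural-log transformed first (zero densities then raise).
    The statistic is island-minus-mainland, so positive t means denser
    islands; swapping group order flips the sign.
    """
    validate_records(records)
    obs = records[records["region"] != "background"]
    island = obs.loc[obs["is_island"], "density"].to_numpy(dtype=float)
    mainland = obs.loc[~obs["is_island"], "density"].to_numpy(dtype=float)
    if island.size < 2 or mainland.size < 2:
        raise InsufficientDataError("need >= 2 records in each of island and mainland")
    if log_scale:
        if (island <= 0).any() or (mainland <= 0).any():
            raise ValueError("log scale requires strictly positive densities")
        island, mainland = np.log(island), np.log(mainland)
    res = stats.ttest_ind(island, mainland, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean1=float(island.mean()),
        se1=float(island.std(ddof=1) / math.sqrt(island.size)),
        mean2=float(mainland.mean()),
        se2=float(mainland.std(ddof=1) / math.sqrt(mainland.size)),
    )


def welch_from_summaries(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> WelchResult:
    """Welch t-test from group summaries (means and standard errors).

    t = (m1 - m2) / sqrt(se1^2 + se2^2), with Welch-Satterthwaite
    df = (se1^2 + se2^2)^2 / (se1^4/(n1-1) + se2^4/(n2-1)).  When one
    group's SE dominates, df approaches that group's n - 1.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need n >= 2 per group")
    v = se1**2 + se2**2
    if v <= 0:
        raise ValueError("zero standard errors")
    t = (mean1 - mean2) / math.sqrt(v)
    df = v**2 / (se1**4 / (n1 - 1) + se2**4 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=t, df=df, p=p, mean1=mean1, se1=se1, mean2=mean2, se2=se2)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_background(
    native_polygon: Polygon,
    n_native_estimates: int,
    seed: int = 0,
    buffer_inner_km: float = 100.0,
    buffer_outer_km: float = 1000.0,
) -> pd.DataFrame:
    """Zero-density background records from a ring around the native range.

    The ring is the planar buffer of the native polygon at the outer
    distance minus the buffer at the inner distance.  The number of
    points is round(n_native * area(ring) / area(native)) (half-up),
    and points are uniform over the ring (rejection sampling from the
    ring's bounding box).
    """
    if not (0 < buffer_inner_km < buffer_outer_km):
        raise ValueError("need 0 < inner buffer < outer buffer")
    if native_polygon is None or not native_polygon.is_valid or native_polygon.area <= 0:
        raise ValueError("native polygon must be valid with positive area")
    ring = native_polygon.buffer(buffer_outer_km).difference(
        native_polygon.buffer(buffer_inner_km)
    )
    n_points = _round_half_up(n_native_estimates * ring.area / native_polygon.area)
    rng = np.random.default_rng((seed, 0xB6))
    minx, miny, maxx, maxy = ring.bounds
    xs: list[float] = []
    ys: list[float] = []
    while len(xs) < n_points:
        cand_x = rng.uniform(minx, maxx, size=max(64, n_points))
        cand_y = rng.uniform(miny, maxy, size=max(64, n_points))
        for x, y in zip(cand_x, cand_y):
            if len(xs) >= n_points:
                break
            if ring.contains(Point(x, y)):
                xs.append(float(x))
                ys.append(float(y))
    return pd.DataFrame(
        {
            "id": [f"bg{i:04d}" for i in range(n_points)],
            "x": xs,
            "y": ys,
            "density": 0.0,
            "is_island": False,
            "region": "background",
            "site_key": [f"bg{i:04d}" for i in range(n_points)],
        },
        columns=RECORD_COLUMNS,
    )
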