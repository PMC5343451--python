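"""From rasters and records to the standardized analysis table.

Covariates are summarized at candidate spatial scales with a circular
moving-window (focal) mean, the best scale and functional form per
covariate are chosen by AICc on univariate fits, the response is the
natural log of density (plus a configurable offset for zero-density
background records), columns are centered and scaled, and highly
correlated covariates (|Pearson r| > 0.70 by default) are pruned
greedily, keeping the member with the stronger univariate association
with the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mmi import DegenerateFitError, TermBlock, compute_aicc, fit_ols
from .raster import RasterGrid

__all__ = [
    "CovariateSpec",
    "DesignTable",
    "default_analysis_specs",
    "focal_mean",
    "extract_covariates",
    "select_scale",
    "standardize",
    "prune_correlated",
    "build_blocks",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Analysis role of one covariate: candidate window radii (km),
    whether a quadratic term is considered, and the predicted sign."""

    name: str
    category: str
    candidate_radii_km: tuple[float, ...] = (10.0, 40.0)
    allow_quadratic: bool = False
    expected_sign: str = "positive"  # positive | negative | quadratic

    def __post_init__(self) -> None:
        if not self.candidate_radii_km:
            raise ValueError(f"{self.name!r}: need at least one candidate radius")


def default_analysis_specs() -> list[CovariateSpec]:
    """The retained landscape-variable roster of the global analysis:
    vegetation fractions summarized at 10 km, climate and predation at
    40 km; potential evapotranspiration and agriculture curvilinear."""
    return [
        CovariateSpec("pet", "abiotic-climate", (40.0,), allow_quadratic=True, expected_sign="quadratic"),
        CovariateSpec("carnivore", "biotic-predation", (40.0,), expected_sign="negative"),
        CovariateSpec("precip_wet", "abiotic-climate", (40.0,), expected_sign="positive"),
        CovariateSpec("unvegetated", "biotic-vegetation", (10.0,), expected_sign="negative"),
        CovariateSpec("agriculture", "biotic-vegetation", (10.0,), allow_quadratic=True, expected_sign="quadratic"),
        CovariateSpec("precip_dry", "abiotic-climate", (40.0,), expected_sign="positive"),
        CovariateSpec("forest", "biotic-vegetation", (10.0,), expected_sign="positive"),
    ]


def _disc_offsets(radius_km: float, cell_size: float) -> np.ndarray:
    """0/1 kernel over cell offsets whose center distance is <= radius."""
    r_cells = int(np.floor(radius_km / cell_size))
    size = 2 * r_cells + 1
    di, dj = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
    dist2 = (di.astype(float) ** 2 + dj.astype(float) ** 2) * cell_size**2
    return (dist2 <= radius_km**2 + 1e-9).astype(float).reshape(size, size)


def focal_mean(grid: RasterGrid, radius_km: float) -> RasterGrid:
    """Circular moving-window mean.

    Each output cell is the mean over all cells whose centers lie
    within ``radius_km`` of that cell's center (inclusive).  NODATA
    (NaN) cells are left out of their neighbours' means; a cell with an
    all-NODATA neighbourhood is NODATA.  The operator is linear in the
    input grid.
    """
    if radius_km < 0:
        raise ValueError("radius must be >= 0")
    from scipy.ndimage import convolve

    kernel = _disc_offsets(radius_km, grid.cell_size)
    valid = np.isfinite(grid.values).astype(float)
    vals = np.where(valid > 0, grid.values, 0.0)
    total = convolve(vals, kernel, mode="constant", cval=0.0)
    count = convolve(valid, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(count > 0, total / count, np.nan)
    return grid.copy_with(out)


def extract_covariates(
    records: pd.DataFrame,
    grids_by_radius: dict[str, dict[float, RasterGrid]],
) -> pd.DataFrame:
    """One row per record, one column per (covariate, radius) pair.

    ``grids_by_radius[name][radius]`` is the focal-mean surface of
    covariate ``name`` at that radius; the value is read at the record's
    cell.  Column names are ``"{name}@{radius:g}km"``.
    """
    out = pd.DataFrame(index=records.index)
    for name, by_radius in grids_by_radius.items():
        for radius, grid in by_radius.items():
            col = [grid.value_at(x, y) for x, y in zip(records["x"], records["y"])]
            out[f"{name}@{radius:g}km"] = col
    return out


@dataclass
class ScaleChoice:
    radius_km: float
    form: str  # "linear" | "quadratic"
    aicc_table: dict[tuple[float, str], float] = field(default_factory=dict)


def select_scale(
    response: np.ndarray,
    candidate_columns: dict[float, np.ndarray],
    spec: CovariateSpec,
) -> ScaleChoice:
    """Pick the covariate's window radius and functional form by AICc.

    Fits a univariate model per candidate radius — linear always, plus
    a main+quadratic pair when the spec allows a curvilinear form — and
    returns the combination with minimal AICc.  Ties break toward the
    smaller radius, then the linear form.  Scale choice is invariant to
    affine rescaling of the candidate columns (standardization happens
    inside the fit comparison).
    """
    y = np.asarray(response, dtype=float)
    n = y.size
    table: dict[tuple[float, str], float] = {}
    for radius in sorted(spec.candidate_radii_km):
        raw = np.asarray(candidate_columns[radius], dtype=float)
        sd = raw.std(ddof=0)
        if sd == 0:
            raise DegenerateFitError(f"{spec.name!r} at {radius} km: constant column")
        z = (raw - raw.mean()) / sd
        forms = {"linear": z[:, None]}
        if spec.allow_quadratic:
            forms["quadratic"] = TermBlock.from_standardized(spec.name, z, quadratic=True).columns
        for form, X in forms.items():
            fit = fit_ols(y, X)
            K = 1 + fit.p + 1
            table[(radius, form)] = compute_aicc(fit.logL, K, n)
    best = min(table.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1] != "linear"))
    (radius, form), _ = best
    return ScaleChoice(radius_km=radius, form=form, aicc_table=table)


@dataclass
class DesignTable:
    """Standardized analysis table.

    response is ln(density + log_offset); every column is centered and
    scaled by its own training mean/SD, retained in ``scaling`` (keys
    for quadratic columns, ``"name^2"``, refer to the square of the
    standardized main column).  ``chosen_radius`` records the selected
    window per covariate.
    """

    response: np.ndarray
    columns: pd.DataFrame
    scaling: dict[str, tuple[float, float]]
    log_offset: float
    chosen_radius: dict[str, float] = field(default_factory=dict)
    chosen_form: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.response.size

    def unstandardize(self, name: str, z: np.ndarray) -> np.ndarray:
        mean, sd = self.scaling[name]
        return z * sd + mean


def standardize(
    raw: pd.DataFrame,
    density: np.ndarray,
    log_offset: float = 1.0,
    chosen_radius: dict[str, float] | None = None,
    chosen_form: dict[str, str] | None = None,
) -> DesignTable:
    """Log-transform the response and center/scale every covariate column."""
    dens = np.asarray(density, dtype=float)
    if (dens < 0).any():
        raise ValueError("densities must be >= 0")
    if log_offset == 0 and (dens == 0).any():
        raise ValueError("zero density requires a positive log offset")
    if log_offset < 0:
        raise ValueError("log offset must be >= 0")
    response = np.log(dens + log_offset)
    cols = {}
    scaling: dict[str, tuple[float, float]] = {}
    for name in raw.columns:
        v = raw[name].to_numpy(dtype=float)
        mean, sd = float(v.mean()), float(v.std(ddof=0))
        if sd == 0:
            raise DegenerateFitError(f"column {name!r} is constant")
        cols[name] = (v - mean) / sd
        scaling[name] = (mean, sd)
    return DesignTable(
        response=response,
        columns=pd.DataFrame(cols, index=raw.index),
        scaling=scaling,
        log_offset=float(log_offset),
        chosen_radius=dict(chosen_radius or {}),
        chosen_form=dict(chosen_form or {}),
    )


def prune_correlated(
    design: DesignTable,
    threshold: float = 0.70,
    priority: dict[str, float] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy exclusion of highly correlated covariates.

    While any pair of retained columns has |Pearson r| > threshold, the
    worst pair is resolved by dropping its lower-priority member.
    Priority defaults to the absolute univariate t-statistic against
    the response, so the covariate more predictive on its own survives.
    Returns (retained names, log of (dropped, kept, r) triples).
    """
    names = list(design.columns.columns)
    if priority is None:
        priority = {}
        for name in names:
            fit = fit_ols(design.response, design.columns[name].to_numpy())
            priority[name] = float(abs(fit.coefficients[1] / fit.standard_errors[1]))
    retained = list(names)
    dropped_log: list[tuple[str, str, float]] = []
    while True:
        if len(retained) < 2:
            break
        corr = design.columns[retained].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        r = float(corr[i, j])
        if abs(r) <= threshold:
            break
        a, b = retained[i], retained[j]
        drop, keep = (a, b) if priority[a] <= priority[b] else (b, a)
        dropped_log.append((drop, keep, r))
        retained.remove(drop)
    return retained, dropped_log


def build_blocks(
    design: DesignTable,
    retained: list[str],
    quadratic_names: set[str] | frozenset[str] = frozenset(),
) -> list[TermBlock]:
    """Assemble term blocks from retained standardized columns.

    Quadratic blocks get a second column — the square of the
    standardized main column, re-standardized — whose scaling is
    recorded in the design table under ``"name^2"`` so prediction can
    rebuild it on new data.
    """
    blocks = []
    for name in retained:
        z = design.columns[name].to_numpy(dtype=float)
        if name in quadratic_names:
            block = TermBlock.from_standardized(name, z, quadratic=True)
            sq = z**2
            design.scaling[f"{name}^2"] = (float(sq.mean()), float(sq.std(ddof=0)))
        else:
            block = TermBlock.from_standardized(name, z)
        blocks.append(block)
    return blocks
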