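"""Potential-density mapping from an averaged model.

Applies model-averaged coefficients to covariate surfaces on the log
scale — standardizing each surface with the training mean/SD, forming
quadratic columns where the model has them — then back-transforms with
exp, removes the log offset, and floors at zero.  A three-class map
(low / moderate / high density) summarizes the continuous surface.
"""

from __future__ import annotations

import numpy as np

from .mmi import AveragedModel
from .raster import GeometryError, RasterGrid

__all__ = ["predict_map", "classify_density", "CLASS_CODES"]

CLASS_CODES = {"low": 0.0, "moderate": 1.0, "high": 2.0}


def predict_map(
    averaged_model: AveragedModel,
    grids: dict[str, RasterGrid],
    scaling: dict[str, tuple[float, float]],
    log_offset: float = 0.0,
    smearing_sigma2: float | None = None,
) -> RasterGrid:
    """Predicted density surface (animals/km^2).

    Per cell: standardize each covariate with its stored training
    (mean, sd), form the block terms (including re-standardized squares
    for quadratic blocks), apply averaged coefficients plus intercept
    on the log scale, back-transform with exp, subtract the log offset,
    and floor at 0.  NODATA (NaN) propagates untouched.  Passing the
    residual variance as ``smearing_sigma2`` applies the log-normal
    mean correction exp(sigma^2 / 2); by default the map is the plain
    back-transform (a "maximal potential density" reading).
    """
    ref: RasterGrid | None = None
    for name in averaged_model.block_names:
        if name not in grids:
            raise GeometryError(f"missing covariate grid {name!r}")
        if name not in scaling:
            raise GeometryError(f"missing scaling metadata for {name!r}")
        if ref is None:
            ref = grids[name]
        else:
            ref.require_same_geometry(grids[name])
    if ref is None:
        raise ValueError("averaged model references no covariates")
    eta = np.full(ref.shape, averaged_model.coefficients["(Intercept)"])
    for name in averaged_model.block_names:
        mean, sd = scaling[name]
        z = (grids[name].values - mean) / sd
        eta = eta + averaged_model.coefficients[name] * z
        if name in averaged_model.quadratic_blocks:
            sq_key = f"{name}^2"
            if sq_key not in scaling:
                raise GeometryError(f"missing scaling metadata for {sq_key!r}")
            mean_sq, sd_sq = scaling[sq_key]
            z2 = (z**2 - mean_sq) / sd_sq
            eta = eta + averaged_model.coefficients[sq_key] * z2
    if smearing_sigma2 is not None:
        eta = eta + smearing_sigma2 / 2.0
    density = np.exp(eta) - log_offset
    density = np.where(np.isnan(density), np.nan, np.maximum(density, 0.0))
    return ref.copy_with(density)


def classify_density(
    density_grid: RasterGrid, breaks: tuple[float, float, float] = (1.0, 6.0, 11.0)
) -> RasterGrid:
    """Three-class density map with codes low=0, moderate=1, high=2.

    ``breaks`` are representative class anchors, not bin edges; the
    edges are their midpoints, so the defaults (1, 6, 11) give
    low [0, 3.5), moderate [3.5, 8.5), high >= 8.5 — every density at
    or above the top anchor is guaranteed high.  Classification is
    monotone in density; NODATA propagates.
    """
    b0, b1, b2 = breaks
    if not (b0 < b1 < b2):
        raise ValueError("breaks must be strictly increasing")
    lo_edge = (b0 + b1) / 2.0
    hi_edge = (b1 + b2) / 2.0
    v = density_grid.values
    cls = np.where(v < lo_edge, CLASS_CODES["low"],
                   np.where(v < hi_edge, CLASS_CODES["moderate"], CLASS_CODES["high"]))
    cls = np.where(np.isnan(v), np.nan, cls)
    return density_grid.copy_with(cls)
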