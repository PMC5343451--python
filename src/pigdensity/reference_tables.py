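"""Published model-selection statistics for the global wild pig density analysis.

The published study compiled 129 field estimates of wild pig (*Sus
scrofa*) density worldwide, added 65 zero-density background locations,
and ranked all subsets of seven landscape term blocks by AICc at
n = 183.  Its printed selection table reports, for the ten best models,
the block membership pattern, the parameter count K, and the maximized
Gaussian log-likelihood.  Those printed numbers are *inputs*: from K,
logL and n the package can regenerate the AICc, delta, and weight
columns and the variable importance values, which exercises the
selection arithmetic against an externally published fixture without
any geodata.

Column conventions match :mod:`pigdensity.mmi`: K counts intercept,
slope coefficients, and the residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mmi import akaike_weights, compute_aicc

__all__ = [
    "REFERENCE_N",
    "REFERENCE_BLOCK_NAMES",
    "REFERENCE_MODEL_ROWS",
    "REFERENCE_IMPORTANCE",
    "REFERENCE_ESTIMATES",
    "ABIOTIC_TOP_WEIGHT",
    "ReferenceRow",
    "recompute_selection_table",
]

# 118 mainland density records + 65 zero-density background points
REFERENCE_N = 183

REFERENCE_BLOCK_NAMES = [
    "pet",            # potential evapotranspiration (main + quadratic)
    "carnivore",      # large carnivore richness
    "precip_wet",     # precipitation of the wettest quarter
    "unvegetated",    # proportion unvegetated area
    "agriculture",    # proportion cropland (main + quadratic)
    "precip_dry",     # precipitation of the driest quarter
    "forest",         # forest canopy cover
]

QUADRATIC_BLOCKS = ("pet", "agriculture")


@dataclass(frozen=True)
class ReferenceRow:
    """One published candidate model: block membership, K, logL."""

    blocks: tuple[str, ...]
    K: int
    logL: float


# The ten best published models, in printed rank order.
REFERENCE_MODEL_ROWS: list[ReferenceRow] = [
    ReferenceRow(("pet", "carnivore", "precip_wet", "unvegetated", "agriculture", "precip_dry"), 10, -108.33),
    ReferenceRow(("pet", "carnivore", "precip_wet", "unvegetated", "agriculture", "precip_dry", "forest"), 11, -108.32),
    ReferenceRow(("pet", "carnivore", "precip_wet", "unvegetated", "agriculture"), 9, -111.98),
    ReferenceRow(("pet", "carnivore", "precip_wet", "unvegetated", "agriculture", "forest"), 10, -111.56),
    ReferenceRow(("pet", "carnivore", "precip_wet", "unvegetated", "precip_dry"), 8, -114.65),
    ReferenceRow(("pet", "carnivore", "precip_wet", "unvegetated", "precip_dry", "forest"), 9, -114.58),
    ReferenceRow(("pet", "carnivore", "precip_wet", "agriculture", "precip_dry"), 9, -114.60),
    ReferenceRow(("pet", "carnivore", "precip_wet", "agriculture", "precip_dry", "forest"), 10, -113.93),
    ReferenceRow(("pet", "carnivore", "precip_wet", "agriculture", "forest"), 9, -116.95),
    ReferenceRow(("pet", "carnivore", "precip_wet", "unvegetated"), 7, -119.64),
]

# Published variable importance values (weights summed over all 128 models).
REFERENCE_IMPORTANCE = {
    "pet": 1.00,
    "carnivore": 1.00,
    "precip_wet": 1.00,
    "unvegetated": 0.99,
    "agriculture": 0.98,
    "precip_dry": 0.92,
    "forest": 0.25,
}

# Published full-model-averaged estimates (standardized scale),
# (coefficient, unconditional SE); quadratic blocks carry (main, quad) pairs.
REFERENCE_ESTIMATES = {
    "pet": {"m": (0.443, 0.056), "q": (-0.226, 0.046)},
    "carnivore": {"m": (-0.243, 0.043)},
    "precip_wet": {"m": (0.233, 0.055)},
    "unvegetated": {"m": (-0.203, 0.061)},
    "agriculture": {"m": (0.236, 0.076), "q": (-0.118, 0.038)},
    "precip_dry": {"m": (0.100, 0.050)},
    "forest": {"m": (-0.001, 0.029)},
}

# Akaike weight of the best abiotic-only model (published); its AICc was 311.30.
ABIOTIC_TOP_WEIGHT = 7.94e-17


def recompute_selection_table(
    rows: list[ReferenceRow] | None = None, n: int = REFERENCE_N
) -> dict:
    """Regenerate AICc, delta, weight, and importance from printed K and logL.

    The unprinted remainder of the 128-model set carries negligible
    weight, so weights are normalized over the printed rows alone.
    """
    if rows is None:
        rows = REFERENCE_MODEL_ROWS
    aicc = np.array([compute_aicc(r.logL, r.K, n) for r in rows])
    deltas, weights = akaike_weights(aicc)
    importance: dict[str, float] = {name: 0.0 for name in REFERENCE_BLOCK_NAMES}
    for r, w in zip(rows, weights):
        for b in r.blocks:
            importance[b] += float(w)
    return {
        "n": n,
        "rows": rows,
        "aicc": aicc,
        "delta": deltas,
        "weight": weights,
        "importance": importance,
    }
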