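"""Model validation: k-fold cross-validation with MSPE and the
observed-vs-predicted Pearson correlation test.

The number of folds defaults to Huberty's rule of thumb: with p
predictors the heuristic held-out fraction is 1 / (1 + sqrt(p - 1)),
giving k = ceil(1 + sqrt(p - 1)) folds.  Prediction error is measured
on the model (log-density) scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .covariates import DesignTable
from .mmi import AveragedModel, ModelSet, TermBlock, enumerate_models, fit_ols, model_average

__all__ = ["CVResult", "huberty_k", "kfold_split", "cross_validate"]


def huberty_k(p: int) -> int:
    """Folds from Huberty's rule of thumb.

    Held-out fraction h = 1 / (1 + sqrt(p - 1)); k = ceil(1/h)
    = ceil(1 + sqrt(p - 1)).  Defined for p >= 2; p = 7 gives k = 4.
    """
    if p < 2:
        raise ValueError("Huberty's rule needs p >= 2 predictors")
    return math.ceil(1.0 + math.sqrt(p - 1.0))


def kfold_split(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Random partition of n indices into k folds of near-equal size.

    Fold sizes differ by at most one; deterministic for a fixed seed.
    Returns an array of fold ids in [0, k).
    """
    if k > n:
        raise ValueError(f"cannot split n = {n} into k = {k} folds")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng((seed, 0xCF))
    assignment = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    start = 0
    for fold in range(k):
        size = base + (1 if fold < extra else 0)
        assignment[perm[start : start + size]] = fold
        start += size
    return assignment


@dataclass
class CVResult:
    """Pooled k-fold cross-validation summary on the log-density scale."""

    k: int
    fold_assignment: np.ndarray
    mspe: float
    per_fold_mspe: list[float]
    pearson_r: float
    t: float
    df: int
    predicted: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _slice_blocks(blocks: list[TermBlock], idx: np.ndarray) -> list[TermBlock]:
    return [TermBlock(b.name, b.columns[idx]) for b in blocks]


def _averaged_coefficient_vector(avg: AveragedModel, blocks: list[TermBlock]) -> np.ndarray:
    names = ["(Intercept)"]
    for b in blocks:
        names.extend(b.column_names)
    return np.array([avg.coefficients[c] for c in names])


def _predict_rows(avg: AveragedModel, blocks: list[TermBlock], idx: np.ndarray) -> np.ndarray:
    X = np.column_stack([b.columns[idx] for b in blocks])
    beta = _averaged_coefficient_vector(avg, blocks)
    return beta[0] + X @ beta[1:]


def cross_validate(
    design: DesignTable,
    blocks: list[TermBlock],
    k: int | None = None,
    seed: int = 0,
    refit_selection: bool = False,
    variant: str = "full",
) -> CVResult:
    """k-fold cross-validation of the model-averaged predictor.

    Per fold, coefficients are re-estimated on the training part only.
    With ``refit_selection`` the whole all-subsets enumeration and
    averaging is repeated inside each training fold; otherwise the
    model structure (candidate-set memberships and Akaike weights) is
    fixed from the full data and only the per-model coefficients are
    refit per fold.  Held-out observations are predicted on the log
    scale; MSPE is their mean squared error, and the pooled
    observed-vs-predicted Pearson r yields t = r sqrt(n-2)/sqrt(1-r^2)
    on n - 2 degrees of freedom.
    """
    y = np.asarray(design.response, dtype=float)
    n = y.size
    if k is None:
        p = sum(1 for _ in blocks)
        k = huberty_k(max(p, 2))
    if k < 2:
        raise ValueError("cross-validation needs k >= 2")
    assignment = kfold_split(n, k, seed)

    fixed_weights: list[tuple[tuple[str, ...], float]] | None = None
    if not refit_selection:
        full_set = enumerate_models(y, blocks)
        fixed_weights = [(m.included_blocks, m.weight) for m in full_set.models]

    predicted = np.full(n, np.nan)
    per_fold_mspe: list[float] = []
    for fold in range(k):
        test = assignment == fold
        train = ~test
        train_idx = np.flatnonzero(train)
        test_idx = np.flatnonzero(test)
        train_blocks = _slice_blocks(blocks, train_idx)
        y_train = y[train_idx]
        if refit_selection:
            mset = enumerate_models(y_train, train_blocks)
        else:
            mset = _refit_fixed_structure(y_train, train_blocks, fixed_weights)  # type: ignore[arg-type]
        avg = model_average(mset, variant=variant)
        predicted[test_idx] = _predict_rows(avg, blocks, test_idx)
        per_fold_mspe.append(float(np.mean((y[test_idx] - predicted[test_idx]) ** 2)))

    mspe = float(np.mean((y - predicted) ** 2))
    r = float(np.corrcoef(y, predicted)[0, 1])
    df = n - 2
    t = r * math.sqrt(df) / math.sqrt(max(1.0 - r**2, 1e-300))
    return CVResult(
        k=k,
        fold_assignment=assignment,
        mspe=mspe,
        per_fold_mspe=per_fold_mspe,
        pearson_r=r,
        t=t,
        df=df,
        predicted=predicted,
    )


def _refit_fixed_structure(
    y_train: np.ndarray,
    train_blocks: list[TermBlock],
    memberships_and_weights: list[tuple[tuple[str, ...], float]],
) -> ModelSet:
    """Refit every candidate model's coefficients on the training rows,
    keeping the full-data Akaike weights."""
    from .mmi import CandidateModel, compute_aicc

    by_name = {b.name: b for b in train_blocks}
    n = y_train.size
    models = []
    for names, weight in memberships_and_weights:
        if names:
            X = np.column_stack([by_name[nm].columns for nm in names])
        else:
            X = None
        fit = fit_ols(y_train, X)
        K = 1 + fit.p + 1
        aicc = compute_aicc(fit.logL, K, n)
        m = CandidateModel(names, fit, K, aicc)
        m.weight = weight
        m.delta = float("nan")
        models.append(m)
    return ModelSet(blocks=train_blocks, models=models)
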