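"""Information-theoretic multimodel inference over term blocks.

This module is the statistical heart of the package: ordinary least
squares with the Gaussian maximum-likelihood log-likelihood, AICc over
all subsets of term blocks, Akaike weights and evidence ratios, full
(zero-substitution) model averaging with unconditional standard errors,
and variable importance values.

A *term block* is a covariate together with its design columns: one
column for a linear covariate, or a linked pair (main effect plus its
re-standardized square) for a covariate with a curvilinear predicted
relationship.  Blocks enter and leave candidate models as a unit, so
a quadratic term never appears without its main effect.

Parameter-count convention
--------------------------
``K`` counts the intercept, every slope coefficient, and the residual
variance.  A model with eight slope columns therefore has K = 10.  This
is the convention under which the published selection tables for the
global wild pig density analysis are internally consistent
(AICc = -2 logL + 2K + 2K(K+1)/(n-K-1) reproduces the printed AICc from
the printed logL at n = 183).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TermBlock",
    "OlsFit",
    "CandidateModel",
    "ModelSet",
    "AveragedModel",
    "DegenerateFitError",
    "fit_ols",
    "compute_aicc",
    "enumerate_models",
    "akaike_weights",
    "evidence_ratio",
    "model_average",
    "variable_importance",
]


class DegenerateFitError(ValueError):
    """Raised for rank-deficient or perfect-fit least-squares problems."""


@dataclass
class TermBlock:
    """A covariate's linked design columns.

    ``columns`` has shape (n, 1) for a linear block or (n, 2) for a
    quadratic block, where the second column is the square of the first,
    re-standardized to mean 0 / sd 1.
    """

    name: str
    columns: np.ndarray
    quadratic: bool = False

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.shape[0] == 1 and self.columns.shape[1] > 2:
            self.columns = self.columns.T
        ncol = self.columns.shape[1]
        if ncol not in (1, 2):
            raise ValueError(f"block {self.name!r}: expected 1 or 2 columns, got {ncol}")
        self.quadratic = ncol == 2

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [self.name] if not self.quadratic else [self.name, f"{self.name}^2"]

    @staticmethod
    def from_standardized(name: str, col: np.ndarray, quadratic: bool = False) -> "TermBlock":
        """Build a block from a standardized main-effect column.

        For a quadratic block the second column is the square of the
        main column, itself re-standardized.
        """
        col = np.asarray(col, dtype=float)
        if not quadratic:
            return TermBlock(name, col[:, None])
        sq = col**2
        sd = sq.std(ddof=0)
        if sd == 0:
            raise DegenerateFitError(f"block {name!r}: squared column is constant")
        sq = (sq - sq.mean()) / sd
        return TermBlock(name, np.column_stack([col, sq]))


@dataclass
class OlsFit:
    """Least-squares fit with Gaussian ML log-likelihood."""

    coefficients: np.ndarray  # intercept first
    standard_errors: np.ndarray
    rss: float
    logL: float
    r2: float
    adjusted_r2: float
    n: int
    p: int  # non-intercept coefficients

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.coefficients[0] + X @ self.coefficients[1:]


def fit_ols(response: np.ndarray, columns: np.ndarray | None) -> OlsFit:
    """Ordinary least squares with an intercept.

    Parameters
    ----------
    response : array, shape (n,)
    columns : array, shape (n, p) or None
        Predictor columns (no intercept column); ``None`` or zero
        columns fits the intercept-only model.

    Returns
    -------
    OlsFit
        With Gaussian maximum-likelihood log-likelihood
        ``logL = -(n/2) (ln 2pi + ln(RSS/n) + 1)`` and
        ``adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)``.
    """
    y = np.asarray(response, dtype=float)
    n = y.size
    if columns is None:
        X = np.ones((n, 1))
    else:
        cols = np.asarray(columns, dtype=float)
        if cols.ndim == 1:
            cols = cols[:, None]
        X = np.column_stack([np.ones(n), cols])
    p = X.shape[1] - 1
    if n < p + 2:  # need >= 1 residual df beyond the intercept
        raise DegenerateFitError(f"n = {n} too small for p = {p} predictors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DegenerateFitError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss <= 0 or (tss > 0 and rss / tss < 1e-14):
        raise DegenerateFitError("perfect fit: RSS = 0, log-likelihood undefined")
    logL = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    # classical OLS covariance, sigma^2 estimated with n - p - 1 df
    sigma2 = rss / (n - p - 1)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return OlsFit(
        coefficients=beta,
        standard_errors=se,
        rss=rss,
        logL=float(logL),
        r2=r2,
        adjusted_r2=adj_r2,
        n=n,
        p=p,
    )


def compute_aicc(logL: float, K: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 logL + 2K + 2K(K + 1) / (n - K - 1), defined for n > K + 1.
    """
    if n <= K + 1:
        raise ValueError(f"AICc undefined: n = {n} <= K + 1 = {K + 1}")
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deltas and Akaike weights for a set of AICc values.

    ``delta_i = AICc_i - min(AICc)``;
    ``w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)``.
    The shift by the minimum makes the exponentials overflow-safe even
    for deltas of many tens of units.
    """
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AICc value")
    if not np.all(np.isfinite(a)):
        raise ValueError("AICc values must be finite")
    deltas = a - a.min()
    raw = np.exp(-deltas / 2.0)
    return deltas, raw / raw.sum()


def evidence_ratio(weight_a: float, weight_b: float) -> float:
    """Relative support of model a over model b, w_a / w_b."""
    if weight_b <= 0:
        raise ZeroDivisionError("evidence ratio undefined for zero denominator weight")
    return weight_a / weight_b


@dataclass
class CandidateModel:
    """One subset of term blocks with its fit and selection statistics."""

    included_blocks: tuple[str, ...]
    fit: OlsFit
    K: int
    aicc: float
    delta: float = np.nan
    weight: float = np.nan

    def contains(self, block_name: str) -> bool:
        return block_name in self.included_blocks


@dataclass
class ModelSet:
    """All candidate models over a fixed block roster, sorted by AICc."""

    blocks: list[TermBlock]
    models: list[CandidateModel]
    excluded: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def __len__(self) -> int:
        return len(self.models)

    @property
    def best(self) -> CandidateModel:
        return self.models[0]


MAX_BLOCKS = 20


def enumerate_models(response: np.ndarray, blocks: list[TermBlock]) -> ModelSet:
    """Fit every subset of term blocks (including intercept-only).

    Each block contributes all of its columns or none of them.  Models
    are ranked ascending by AICc; deltas and Akaike weights are filled
    over the full enumeration.  Rank-deficient subsets are excluded and
    logged in ``ModelSet.excluded``.
    """
    if not blocks:
        raise ValueError("need at least one term block")
    if len(blocks) > MAX_BLOCKS:
        raise ValueError(f"refusing to enumerate 2^{len(blocks)} models")
    y = np.asarray(response, dtype=float)
    n = y.size
    models: list[CandidateModel] = []
    excluded: list[tuple[tuple[str, ...], str]] = []
    for r in range(len(blocks) + 1):
        for subset in itertools.combinations(range(len(blocks)), r):
            names = tuple(blocks[i].name for i in subset)
            if subset:
                X = np.column_stack([blocks[i].columns for i in subset])
            else:
                X = None
            try:
                fit = fit_ols(y, X)
            except DegenerateFitError as exc:
                excluded.append((names, str(exc)))
                continue
            K = 1 + fit.p + 1  # intercept + slopes + residual variance
            aicc = compute_aicc(fit.logL, K, n)
            models.append(CandidateModel(names, fit, K, aicc))
    if not models:
        raise DegenerateFitError("every candidate model was rank deficient")
    models.sort(key=lambda m: (m.aicc, m.K, m.included_blocks))
    deltas, weights = akaike_weights([m.aicc for m in models])
    for m, d, w in zip(models, deltas, weights):
        m.delta = float(d)
        m.weight = float(w)
    return ModelSet(blocks=list(blocks), models=models, excluded=excluded)


@dataclass
class AveragedModel:
    """Model-averaged coefficients with unconditional SEs and importances.

    Coefficient keys are column names (block name, plus ``name^2`` for
    the quadratic column of a curvilinear block) plus ``"(Intercept)"``.
    """

    coefficients: dict[str, float]
    unconditional_se: dict[str, float]
    importance: dict[str, float]
    block_names: list[str]
    quadratic_blocks: list[str]
    scaling: dict | None = None
    log_offset: float = 0.0
    variant: str = "full"

    def coefficient_vector(self, column_names: list[str]) -> np.ndarray:
        return np.array([self.coefficients[c] for c in column_names])


def variable_importance(model_set: ModelSet) -> dict[str, float]:
    """Importance of each block: sum of Akaike weights of the models containing it."""
    imp = {name: 0.0 for name in model_set.block_names}
    for m in model_set.models:
        for name in m.included_blocks:
            imp[name] += m.weight
    return imp


def model_average(
    model_set: ModelSet,
    variant: str = "full",
    se_form: str = "sum-of-roots",
) -> AveragedModel:
    """Average coefficients over a model set with Akaike weights.

    variant
        ``"full"`` (default): a coefficient is treated as 0, with zero
        variance, in every model excluding its block, so weak terms
        shrink toward zero.  ``"conditional"``: averages only over the
        models containing the block, renormalizing the weights.
    se_form
        ``"sum-of-roots"`` (default): unconditional
        SE = sum_i w_i sqrt(var_i + (b_i - bbar)^2).
        ``"root-of-sum"``: SE = sqrt(sum_i w_i (var_i + (b_i - bbar)^2)).
    """
    if not model_set.models:
        raise ValueError("empty model set")
    if variant not in ("full", "conditional"):
        raise ValueError(f"unknown averaging variant {variant!r}")
    if se_form not in ("sum-of-roots", "root-of-sum"):
        raise ValueError(f"unknown SE form {se_form!r}")

    # per-model coefficient lookup by column name
    col_names: list[str] = ["(Intercept)"]
    col_to_block: dict[str, str] = {}
    for b in model_set.blocks:
        for cn in b.column_names:
            col_names.append(cn)
            col_to_block[cn] = b.name

    weights = np.array([m.weight for m in model_set.models])
    n_models = len(model_set.models)
    est = np.zeros((n_models, len(col_names)))
    var = np.zeros((n_models, len(col_names)))
    present = np.zeros((n_models, len(col_names)), dtype=bool)
    present[:, 0] = True  # intercept in every model
    for i, m in enumerate(model_set.models):
        est[i, 0] = m.fit.coefficients[0]
        var[i, 0] = m.fit.standard_errors[0] ** 2
        j = 1
        for bname in m.included_blocks:
            block = next(b for b in model_set.blocks if b.name == bname)
            for cn in block.column_names:
                k = col_names.index(cn)
                est[i, k] = m.fit.coefficients[j]
                var[i, k] = m.fit.standard_errors[j] ** 2
                present[i, k] = True
                j += 1

    coefs: dict[str, float] = {}
    ses: dict[str, float] = {}
    for k, cn in enumerate(col_names):
        if variant == "full" or cn == "(Intercept)":
            w = weights
            b = np.where(present[:, k], est[:, k], 0.0)
            v = np.where(present[:, k], var[:, k], 0.0)
        else:
            mask = present[:, k]
            if not mask.any():
                coefs[cn] = 0.0
                ses[cn] = 0.0
                continue
            w = weights[mask] / weights[mask].sum()
            b = est[mask, k]
            v = var[mask, k]
        bbar = float(w @ b)
        spread = (b - bbar) ** 2
        if se_form == "sum-of-roots":
            se = float(w @ np.sqrt(v + spread))
        else:
            se = float(np.sqrt(w @ (v + spread)))
        coefs[cn] = bbar
        ses[cn] = se

    return AveragedModel(
        coefficients=coefs,
        unconditional_se=ses,
        importance=variable_importance(model_set),
        block_names=model_set.block_names,
        quadratic_blocks=[b.name for b in model_set.blocks if b.quadratic],
        variant=variant,
    )
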