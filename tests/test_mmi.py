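"""Unit and property tests for the multimodel-inference core."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm

from pigdensity.mmi import (
    DegenerateFitError,
    TermBlock,
    akaike_weights,
    compute_aicc,
    enumerate_models,
    evidence_ratio,
    fit_ols,
    model_average,
    variable_importance,
)
from pigdensity.synthetic import simulate_design

# ---------------------------------------------------------------- fit_ols


def test_ols_hand_solved_normal_equations():
    # y = {1, 2, 4} on x = {0, 1, 2}: slope 1.5, intercept 5/6, RSS 1/6
    fit = fit_ols(np.array([1.0, 2.0, 4.0]), np.array([0.0, 1.0, 2.0]))
    assert fit.coefficients[0] == pytest.approx(5 / 6, abs=1e-12)
    assert fit.coefficients[1] == pytest.approx(1.5, abs=1e-12)
    assert fit.rss == pytest.approx(1 / 6, abs=1e-12)


def test_ols_matches_statsmodels_oracle(rng):
    for _ in range(10):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50) + X @ np.array([0.5, -1.0, 0.2])
        fit = fit_ols(y, X)
        sm_fit = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.coefficients, sm_fit.params, atol=1e-8)
        np.testing.assert_allclose(fit.standard_errors, sm_fit.bse, atol=1e-8)
        assert fit.logL == pytest.approx(sm_fit.llf, abs=1e-8)
        assert fit.adjusted_r2 == pytest.approx(sm_fit.rsquared_adj, abs=1e-10)


def test_ols_matches_normal_equations_brute_force(rng):
    X = rng.normal(size=(50, 3))
    y = rng.normal(size=50)
    Xi = np.column_stack([np.ones(50), X])
    beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
    fit = fit_ols(y, X)
    np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)


def test_ols_degenerate_inputs(rng):
    x = rng.normal(size=20)
    with pytest.raises(DegenerateFitError):  # duplicated column: rank deficient
        fit_ols(rng.normal(size=20), np.column_stack([x, x]))
    with pytest.raises(DegenerateFitError):  # constant response: RSS = 0, logL undefined
        fit_ols(np.zeros(20), x)
    with pytest.raises(DegenerateFitError):  # exact linear response: perfect fit
        fit_ols(2.0 * x + 1.0, x)


# ------------------------------------------------------------ compute_aicc


@pytest.mark.parametrize(
    "logL,K,n,expected",
    [
        # published selection table rows reproduce from logL and K at n = 183
        (-108.33, 10, 183, 237.94),
        (-108.32, 11, 183, 240.18),
        (-111.98, 9, 183, 243.00),
        (0.0, 1, 100, 2 + 4 / 98),
    ],
)
def test_aicc_formula(logL, K, n, expected):
    assert compute_aicc(logL, K, n) == pytest.approx(expected, abs=0.005)


def test_aicc_undefined_for_tiny_n():
    with pytest.raises(ValueError):
        compute_aicc(-10.0, 5, 6)


# ---------------------------------------------------------- akaike weights


def test_weights_basics():
    _, w = akaike_weights([123.4])
    assert w[0] == 1.0
    _, w = akaike_weights([10.0, 10.0])
    np.testing.assert_allclose(w, [0.5, 0.5])


def test_weights_reproduce_published_column():
    deltas = np.array([0, 2.24, 5.06, 6.46, 8.20, 10.26, 10.31, 11.20, 15.01, 15.99])
    _, w = akaike_weights(deltas)  # deltas are AICc values up to a shared constant
    np.testing.assert_allclose(
        np.round(w, 2), [0.68, 0.22, 0.05, 0.03, 0.01, 0.0, 0.0, 0.0, 0.0, 0.0]
    )


def test_weights_sum_to_one_and_shift_invariant(rng):
    a = rng.uniform(100, 400, size=30)
    d1, w1 = akaike_weights(a)
    d2, w2 = akaike_weights(a + 57.3)
    assert w1.sum() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(w1, w2, atol=1e-12)
    np.testing.assert_allclose(d1, d2, atol=1e-9)


def test_weights_survive_huge_deltas():
    # a 73-unit spread between model families must not underflow to 0/0
    _, w = akaike_weights([237.94, 311.30])
    assert w[0] > 0.999999
    assert w[1] > 0.0


# ----------------------------------------------------------- evidence ratio


def test_evidence_ratio_exceeds_thousand_for_published_weights():
    ratio = evidence_ratio(0.68, 7.94e-17)
    assert ratio > 1_000
    assert ratio == pytest.approx(8.56e15, rel=0.01)


def test_evidence_ratio_identity_and_delta_form():
    assert evidence_ratio(0.4, 0.4) == 1.0
    _, w = akaike_weights([100.0, 104.0])
    assert evidence_ratio(w[0], w[1]) == pytest.approx(np.exp(4.0 / 2.0), rel=1e-12)
    with pytest.raises(ZeroDivisionError):
        evidence_ratio(0.5, 0.0)


# ------------------------------------------------------- enumerate_models


@pytest.fixture
def paper_structure():
    """Seven blocks, two of them quadratic, at the study's sample size."""
    return simulate_design(n=183, seed=11)


def test_enumeration_counts_and_K(paper_structure):
    y, blocks, _ = paper_structure
    mset = enumerate_models(y, blocks)
    assert len(mset) == 2**7
    by_subset = {frozenset(m.included_blocks): m for m in mset.models}
    full = by_subset[frozenset(b.name for b in blocks)]
    assert full.K == 11  # 9 slope columns + intercept + residual variance
    no_forest = by_subset[frozenset(b.name for b in blocks) - {"forest"}]
    assert no_forest.K == 10


def test_enumeration_fills_sorted_deltas_and_weights(paper_structure):
    y, blocks, _ = paper_structure
    mset = enumerate_models(y, blocks)
    aiccs = [m.aicc for m in mset.models]
    assert aiccs == sorted(aiccs)
    assert mset.models[0].delta == 0.0
    assert sum(m.weight for m in mset.models) == pytest.approx(1.0, abs=1e-12)


def test_adding_a_block_never_decreases_logL(paper_structure):
    y, blocks, _ = paper_structure
    mset = enumerate_models(y, blocks)
    by_subset = {frozenset(m.included_blocks): (m.fit.logL) for m in mset.models}
    for subset, logL in by_subset.items():
        for b in blocks:
            if b.name not in subset:
                assert by_subset[subset | {b.name}] >= logL - 1e-9


def test_enumeration_matches_refit_from_scratch_brute_force(rng):
    """Independent oracle: for <= 4 blocks, every subset refit via the
    normal equations gives the same AICc ranking and weights."""
    n = 60
    X = rng.normal(size=(n, 4))
    X = (X - X.mean(0)) / X.std(0)
    y = 0.5 * X[:, 0] - 0.8 * X[:, 2] + rng.normal(size=n)
    blocks = [TermBlock.from_standardized(f"b{i}", X[:, i]) for i in range(4)]
    mset = enumerate_models(y, blocks)

    oracle = []
    for r in range(5):
        for subset in itertools.combinations(range(4), r):
            Xi = np.column_stack([np.ones(n)] + [X[:, i] for i in subset])
            beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
            rss = float(np.sum((y - Xi @ beta) ** 2))
            logL = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1)
            K = len(subset) + 2
            aicc = -2 * logL + 2 * K + 2 * K * (K + 1) / (n - K - 1)
            oracle.append((frozenset(f"b{i}" for i in subset), aicc))
    oracle_by_subset = dict(oracle)
    for m in mset.models:
        assert m.aicc == pytest.approx(oracle_by_subset[frozenset(m.included_blocks)], abs=1e-8)


def test_aicc_ordering_invariant_to_affine_rescaling(rng):
    n = 80
    X = rng.normal(size=(n, 3))
    y = X @ np.array([0.4, 0.0, -0.6]) + rng.normal(size=n)
    blocks_a = [TermBlock(f"b{i}", X[:, i : i + 1]) for i in range(3)]
    X2 = X * np.array([10.0, 0.2, 3.0]) + np.array([5.0, -1.0, 100.0])
    blocks_b = [TermBlock(f"b{i}", X2[:, i : i + 1]) for i in range(3)]
    order_a = [m.included_blocks for m in enumerate_models(y, blocks_a).models]
    order_b = [m.included_blocks for m in enumerate_models(y, blocks_b).models]
    assert order_a == order_b


def test_rank_deficient_subset_flagged_and_excluded(rng):
    x = rng.normal(size=40)
    blocks = [TermBlock("a", x[:, None]), TermBlock("dup", x[:, None].copy())]
    y = x + rng.normal(size=40)
    mset = enumerate_models(y, blocks)
    assert len(mset) == 3  # {}, {a}, {dup}; {a, dup} is rank deficient
    assert any(set(names) == {"a", "dup"} for names, _ in mset.excluded)


# ----------------------------------------------- averaging and importance


def _two_model_set(rng, w0=0.75):
    """Hand-checkable set: term 'a' in model 0 only; weights fixed."""
    n = 40
    x = (lambda v: (v - v.mean()) / v.std())(rng.normal(size=n))
    y = 2.0 * x + rng.normal(size=n) * 0.1
    blocks = [TermBlock("a", x[:, None])]
    mset = enumerate_models(y, blocks)
    for m in mset.models:
        m.weight = w0 if m.included_blocks else 1.0 - w0
    return mset


def test_full_average_hand_computation(rng):
    mset = _two_model_set(rng)
    with_a = next(m for m in mset.models if m.included_blocks)
    beta = with_a.fit.coefficients[1]
    avg = model_average(mset, variant="full")
    assert avg.coefficients["a"] == pytest.approx(0.75 * beta, rel=1e-12)


def test_conditional_average_ignores_absent_models(rng):
    mset = _two_model_set(rng)
    with_a = next(m for m in mset.models if m.included_blocks)
    avg = model_average(mset, variant="conditional")
    assert avg.coefficients["a"] == pytest.approx(with_a.fit.coefficients[1], rel=1e-12)


def test_single_model_average_returns_its_fit(rng):
    n = 50
    X = rng.normal(size=(n, 2))
    y = X @ np.array([1.0, -0.5]) + rng.normal(size=n)
    blocks = [TermBlock(f"b{i}", X[:, i : i + 1]) for i in range(2)]
    mset = enumerate_models(y, blocks)
    full = next(m for m in mset.models if len(m.included_blocks) == 2)
    for m in mset.models:
        m.weight = 1.0 if m is full else 0.0
    avg = model_average(mset)
    assert avg.coefficients["b0"] == pytest.approx(full.fit.coefficients[1], rel=1e-12)
    assert avg.unconditional_se["b0"] == pytest.approx(full.fit.standard_errors[1], rel=1e-12)


def test_averaged_coefficient_in_convex_hull(paper_structure):
    y, blocks, _ = paper_structure
    mset = enumerate_models(y, blocks)
    avg = model_average(mset)
    for b in blocks:
        per_model = [0.0]
        for m in mset.models:
            if b.name in m.included_blocks:
                j = 1 + sum(
                    next(bb for bb in blocks if bb.name == nm).n_columns
                    for nm in m.included_blocks[: m.included_blocks.index(b.name)]
                )
                per_model.append(m.fit.coefficients[j])
        assert min(per_model) - 1e-12 <= avg.coefficients[b.name] <= max(per_model) + 1e-12


def test_se_forms_ordered_by_jensen(paper_structure):
    y, blocks, _ = paper_structure
    mset = enumerate_models(y, blocks)
    a = model_average(mset, se_form="sum-of-roots")
    b = model_average(mset, se_form="root-of-sum")
    for name in a.unconditional_se:
        assert a.unconditional_se[name] <= b.unconditional_se[name] + 1e-12


def test_importance_sums_weights_of_containing_models(paper_structure):
    y, blocks, _ = paper_structure
    mset = enumerate_models(y, blocks)
    imp = variable_importance(mset)
    for name, value in imp.items():
        direct = sum(m.weight for m in mset.models if name in m.included_blocks)
        assert value == pytest.approx(direct, abs=1e-12)
        assert 0.0 <= value <= 1.0


def test_block_in_every_model_has_importance_one(rng):
    mset = _two_model_set(rng)
    for m in mset.models:  # force 'a' present in all surviving models
        m.weight = 1.0 if m.included_blocks else 0.0
    assert variable_importance(mset)["a"] == pytest.approx(1.0)
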