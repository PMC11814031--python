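"""Permutation GLM, rank correlation and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from lcnm.group_stats import (
    DesignError,
    SchemaError,
    adjust_moca,
    build_design,
    descriptive_tests,
    levene_test,
    pairwise_contrasts,
    permutation_ancova,
    posthoc_pairwise,
    spearman_corr,
)

from oracles import exhaustive_anova_p, exhaustive_two_group_t_p, spearman_exact_p


# ---------------------------------------------------------------------------
# design and omnibus
# ---------------------------------------------------------------------------

def test_design_shapes_and_rank():
    groups = np.repeat(["HC", "MSA", "PD"], 4)
    age = np.arange(12.0)
    X, Z, levels = build_design(groups, age)
    assert X.shape == (12, 4) and Z.shape == (12, 2)
    assert levels == ["HC", "MSA", "PD"]
    with pytest.raises(ValueError):
        build_design(np.array(["a"] * 5 + ["b"]))  # group with < 2 members


def test_constant_outcome_gives_zero_F_p_one():
    groups = np.repeat(["HC", "MSA", "PD"], 3)
    res = permutation_ancova(np.ones(9), groups, n_perm=200, seed=0)
    assert res.observed == 0.0
    assert res.p_value == 1.0


def test_observed_F_matches_parametric_ancova(rng):
    """Observed statistic equals the classic F from nested OLS fits."""
    groups = np.repeat(["HC", "MSA", "PD"], 10)
    age = rng.uniform(45, 80, 30)
    y = rng.normal(0, 1, 30) + 0.02 * age
    res = permutation_ancova(y, groups, covariates=age, n_perm=100, seed=0)
    import statsmodels.api as sm

    X_full = np.column_stack([np.eye(3)[np.repeat(np.arange(3), 10)], age])
    X_red = np.column_stack([np.ones(30), age])
    rss_f = sm.OLS(y, X_full).fit().ssr
    rss_r = sm.OLS(y, X_red).fit().ssr
    want = ((rss_r - rss_f) / 2) / (rss_f / (30 - 4))
    assert res.observed == pytest.approx(want, rel=1e-10)
    assert res.df == (2.0, 26.0)


def test_exhaustive_enumeration_matches_anova_oracle(rng):
    """n=9 (3/3/3) no covariate: exact p equals full 1680-relabeling enumeration."""
    y = rng.normal(0, 1, 9)
    groups = np.repeat(["HC", "MSA", "PD"], 3)
    res = permutation_ancova(y, groups, n_perm=10_000, seed=1)
    assert res.exhaustive and res.n_perm == 1680
    want_p, total = exhaustive_anova_p(y, groups)
    assert total == 1680
    assert res.p_value == pytest.approx(want_p, abs=1e-12)


def test_monte_carlo_agrees_with_exhaustive_within_3se(rng):
    y = rng.normal(0, 1, 9) + np.repeat([0.0, 0.8, 0.0], 3)
    groups = np.repeat(["HC", "MSA", "PD"], 3)
    exact = permutation_ancova(y, groups, n_perm=10_000, seed=0)
    mc = permutation_ancova(y, groups, n_perm=10_000, seed=7, force_monte_carlo=True)
    se = np.sqrt(exact.p_value * (1 - exact.p_value) / mc.n_perm)
    assert abs(mc.p_value - exact.p_value) < 3 * se + 1e-4


def test_p_value_bounds_invariant(rng):
    groups = np.repeat(["HC", "MSA"], 5)
    for _ in range(5):
        y = rng.normal(0, 1, 10)
        r = permutation_ancova(y, groups, covariates=rng.uniform(0, 1, 10),
                               n_perm=99, seed=3)
        assert 1 / (r.n_perm + 1) <= r.p_value <= 1.0


def test_singular_design_raises():
    groups = np.repeat(["HC", "MSA"], 4)
    collinear = (groups == "HC").astype(float)  # duplicates a group indicator
    with pytest.raises(DesignError):
        permutation_ancova(np.arange(8.0), groups, covariates=collinear, n_perm=10)


# ---------------------------------------------------------------------------
# post hoc contrasts
# ---------------------------------------------------------------------------

def test_six_contrasts_for_three_groups():
    labels = [f"{a}{d}{b}" for a, b, d in pairwise_contrasts(["HC", "MSA", "PD"])]
    assert labels == ["HC>MSA", "HC<MSA", "HC>PD", "HC<PD", "MSA>PD", "MSA<PD"]


def test_posthoc_direction_symmetry_and_bonferroni(rng):
    groups = np.repeat(["HC", "MSA", "PD"], 8)
    y = rng.normal(0, 1, 24)
    age = rng.uniform(45, 80, 24)
    res = {r.contrast: r for r in posthoc_pairwise(y, groups, covariates=age,
                                                   n_perm=300, seed=5)}
    assert res["HC>MSA"].observed == pytest.approx(-res["HC<MSA"].observed)
    for r in res.values():
        assert r.p_fwer == pytest.approx(min(1.0, 6 * r.p_value))
        assert r.p_fwer >= r.p_value
    # one-tailed p of opposite directions sum to ~1 (within estimator add-one)
    s = res["HC>MSA"].p_value + res["HC<MSA"].p_value
    assert 1.0 <= s <= 1.0 + 2 / 301 + 1e-9


def test_sign_flip_swaps_one_tailed_ps(rng):
    groups = np.repeat(["HC", "MSA"], 6)
    y = rng.normal(0, 1, 12) + (groups == "HC") * 1.0
    a = {r.contrast: r for r in posthoc_pairwise(y, groups, n_perm=10_000, seed=2)}
    b = {r.contrast: r for r in posthoc_pairwise(-y, groups, n_perm=10_000, seed=2)}
    assert a["HC>MSA"].p_value == pytest.approx(b["HC<MSA"].p_value, abs=1e-12)
    assert a["HC<MSA"].p_value == pytest.approx(b["HC>MSA"].p_value, abs=1e-12)


def test_two_group_exhaustive_equals_enumeration_oracle(rng):
    """n=8 (4/4) exhaustive one-tailed t p equals the 70-relabeling enumeration."""
    groups = np.repeat(["HC", "MSA"], 4)
    y = rng.normal(0, 1, 8) + (groups == "HC") * 0.7
    res = {r.contrast: r for r in posthoc_pairwise(y, groups, n_perm=10_000, seed=0)}
    assert res["HC>MSA"].exhaustive and res["HC>MSA"].n_perm == 70
    want, total = exhaustive_two_group_t_p(y, groups, "HC", "MSA")
    assert total == 70
    assert res["HC>MSA"].p_value == pytest.approx(want, abs=1e-12)


def test_bonferroni_arithmetic_example():
    # unadjusted p = 0.02 with 6 tests -> p_FWER = 0.12
    assert min(1.0, 0.02 * 6) == pytest.approx(0.12)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_monotone_and_antisymmetry(rng):
    x = np.sort(rng.normal(size=10))
    y = np.exp(x)  # monotone increasing
    assert spearman_corr(x, y).rho == pytest.approx(1.0)
    assert spearman_corr(x[::-1], y).rho == pytest.approx(-1.0)


def test_spearman_closed_form_tie_free(rng):
    x, y = rng.normal(size=12), rng.normal(size=12)
    rx, ry = ss.rankdata(x), ss.rankdata(y)
    n = 12
    closed = 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n * n - 1))
    assert spearman_corr(x, y).rho == pytest.approx(closed, abs=1e-12)


def test_spearman_matches_scipy_rho_with_ties():
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0])
    assert spearman_corr(x, y).rho == pytest.approx(ss.spearmanr(x, y).statistic, abs=1e-12)


def test_spearman_exact_p_matches_enumeration(rng):
    x, y = rng.normal(size=6), rng.normal(size=6)
    res = spearman_corr(x, y)
    assert res.method == "exact"
    assert res.p_value == pytest.approx(spearman_exact_p(x, y), abs=1e-12)


def test_spearman_large_n_uses_t_approximation(rng):
    x, y = rng.normal(size=40), rng.normal(size=40)
    res = spearman_corr(x, y)
    assert res.method == "t-approx"
    # consistent with scipy's asymptotic p
    assert res.p_value == pytest.approx(ss.spearmanr(x, y).pvalue, rel=0.05)


def test_spearman_constant_input_flagged():
    res = spearman_corr(np.ones(5), np.arange(5.0))
    assert np.isnan(res.rho) and res.flag == "constant-input"


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def test_levene_identical_groups_zero(rng):
    y = rng.normal(0, 1, 10)
    W, p = levene_test(np.r_[y, y], np.repeat(["a", "b"], 10))
    assert W == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        levene_test(np.arange(3.0), np.array(["a", "a", "b"]))


def test_moca_adjustment_rule_and_cap():
    assert adjust_moca(24, 12) == 25
    assert adjust_moca(24, 16) == 24
    assert adjust_moca(30, 10) == 30
    with pytest.raises(ValueError):
        adjust_moca(31, 10)


def _sex_table():
    rows = []
    for grp, (m, f) in {"HC": (7, 11), "MSA": (6, 5), "PD": (11, 7)}.items():
        rows += [{"group": grp, "sex": "M", "age": 60}] * m
        rows += [{"group": grp, "sex": "F", "age": 61}] * f
    return pd.DataFrame(rows)


def test_chi_square_matches_hand_computation():
    """Sex-by-group 2x3 table {7/11, 6/5, 11/7} gives the hand-computed chi2."""
    table = _sex_table()
    counts = pd.crosstab(table["sex"], table["group"]).to_numpy(float)
    expected = counts.sum(1, keepdims=True) * counts.sum(0, keepdims=True) / counts.sum()
    chi2_hand = float(((counts - expected) ** 2 / expected).sum())
    rep = descriptive_tests(table)
    assert rep["tests"]["sex_chi2"]["chi2"] == pytest.approx(chi2_hand, abs=1e-12)
    assert rep["tests"]["sex_chi2"]["chi2"] == pytest.approx(1.848, abs=5e-4)


def test_identical_distributions_give_null_descriptives():
    rows = []
    for grp in ("HC", "MSA"):
        for age in (50, 60, 70):
            rows += [{"group": grp, "sex": "M", "age": age},
                     {"group": grp, "sex": "F", "age": age}]
    rep = descriptive_tests(pd.DataFrame(rows))
    assert rep["tests"]["age_kruskal"]["H"] == pytest.approx(0.0, abs=1e-12)
    assert rep["tests"]["sex_chi2"]["chi2"] == pytest.approx(0.0, abs=1e-12)


def test_missing_columns_raise_schema_error():
    with pytest.raises(SchemaError):
        descriptive_tests(pd.DataFrame({"group": ["a", "b"], "age": [1, 2]}))
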