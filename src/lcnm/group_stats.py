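"""Scalar-level inference on sub-regional LC contrasts.

The centerpiece is a permutation general linear model in the Freedman-Lane
scheme: nuisance covariates (age) are fitted alone, their residuals are
permuted and re-added to the nuisance fit, and the statistic of interest is
recomputed on each permuted response.  The omnibus test is an ANCOVA-type
F for the group factor; post hoc inference uses six one-tailed pairwise t
contrasts with Bonferroni family-wise error control.  When the design has
no nuisance covariates and the number of distinct group relabelings is
within the permutation budget, the null distribution is enumerated
exhaustively instead of sampled.

Descriptive statistics (Kruskal-Wallis, chi-square, Mann-Whitney, Levene's
test in its median-centered Brown-Forsythe form) delegate to scipy; the
Spearman rank correlation is tie-aware with an exact permutation p-value
for small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_PERM = 10_000
POSTHOC_N_TESTS = 6


class DesignError(ValueError):
    """Singular or otherwise unusable design matrix."""


class SchemaError(ValueError):
    """Covariate table is missing required columns."""


@dataclass
class PermutationResult:
    """Outcome of one permutation test."""

    statistic_name: str          # "F" or "t"
    observed: float
    p_value: float
    n_perm: int                  # permutations actually evaluated (excl. observed)
    seed: int | None
    tail: str                    # "one" or "two"
    contrast: str
    df: tuple[float, float] | float | None = None
    p_fwer: float | None = None
    exhaustive: bool = False

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "statistic_name", "observed", "p_value", "n_perm", "seed",
            "tail", "contrast", "p_fwer", "exhaustive")}
        d["df"] = list(self.df) if isinstance(self.df, tuple) else self.df
        return d


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(groups, covariates=None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Cell-means design for the group factor plus nuisance covariates.

    Returns ``(X, Z, levels)`` where ``X`` holds one indicator column per
    group level (sorted) followed by covariate columns, and ``Z`` is the
    reduced (intercept + covariates) nuisance design.
    """
    groups = np.asarray(groups)
    n = len(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for g in levels:
        if int((groups == g).sum()) < 2:
            raise ValueError(f"group '{g}' has fewer than 2 members")
    G = np.column_stack([(groups == g).astype(float) for g in levels])
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariates length does not match number of subjects")
        if not np.all(np.isfinite(C)):
            raise ValueError("covariates contain non-finite values")
    X = np.column_stack([G, C])
    Z = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return X, Z, levels


def _residual_maker(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    return np.eye(n) - M @ np.linalg.pinv(M)


def _rss(Y: np.ndarray, R: np.ndarray) -> np.ndarray:
    # Y: (m, n) rows of responses; R: symmetric idempotent residual maker
    return np.einsum("ij,ij->i", Y @ R, Y)


def _f_stats(Y: np.ndarray, Rx: np.ndarray, Rz: np.ndarray, df1: int, df2: int) -> np.ndarray:
    rss_f = _rss(Y, Rx)
    rss_r = _rss(Y, Rz)
    scale = np.einsum("ij,ij->i", Y, Y) + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    # constant / perfectly-fit responses: no residual variation -> F := 0
    F = np.where(rss_f <= 1e-12 * scale, np.where(rss_r - rss_f <= 1e-12 * scale, 0.0, np.inf), F)
    return F


def _t_stats(Y: np.ndarray, X: np.ndarray, c: np.ndarray, Rx: np.ndarray, df2: int) -> np.ndarray:
    xtx_inv = np.linalg.pinv(X.T @ X)
    w = xtx_inv @ X.T                      # (p, n)
    effect = Y @ (w.T @ c)                 # (m,)
    var_c = float(c @ xtx_inv @ c)
    rss_f = _rss(Y, Rx)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss_f / df2 * var_c)
        t = effect / se
    t = np.where(se == 0, np.sign(effect) * np.inf, t)
    return np.where(np.isnan(t), 0.0, t)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _multinomial_count(counts: list[int]) -> int:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def _exhaustive_assignments(groups: np.ndarray, levels: list[str]) -> np.ndarray:
    """All distinct permutations of y over group positions (one per relabeling).

    Valid when no covariates are present: the statistic is invariant to
    within-group ordering, so one representative index permutation per
    distinct assignment of response indices to groups enumerates the full
    permutation null.
    """
    positions = [np.where(groups == g)[0] for g in levels]
    n = len(groups)
    perms: list[np.ndarray] = []
    perm = np.empty(n, dtype=int)

    def rec(remaining: list[int], level_idx: int) -> None:
        pos = positions[level_idx]
        if level_idx == len(positions) - 1:
            perm[pos] = remaining
            perms.append(perm.copy())
            return
        for chosen in itertools.combinations(remaining, len(pos)):
            perm[pos] = chosen
            rest = [i for i in remaining if i not in set(chosen)]
            rec(rest, level_idx + 1)

    rec(list(range(n)), 0)
    return np.array(perms)


def _freedman_lane_responses(y: np.ndarray, Z: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Permuted responses: nuisance fit plus permuted nuisance residuals."""
    fitted = Z @ (np.linalg.pinv(Z) @ y)
    resid = y - fitted
    return fitted[None, :] + resid[perms]


def _permutation_plan(
    groups: np.ndarray,
    levels: list[str],
    has_covariates: bool,
    n_perm: int,
    seed: int | None,
    force_monte_carlo: bool,
) -> tuple[np.ndarray, bool]:
    n = len(groups)
    counts = [int((groups == g).sum()) for g in levels]
    if not has_covariates and not force_monte_carlo and _multinomial_count(counts) <= n_perm:
        return _exhaustive_assignments(groups, levels), True
    if has_covariates and not force_monte_carlo and math.factorial(n) <= n_perm:
        return np.array(list(itertools.permutations(range(n)))), True
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)]), False


def _perm_pvalue(observed: float, null: np.ndarray, exhaustive: bool) -> float:
    eps = 1e-12 * (1.0 + abs(observed))
    b = int(np.sum(null >= observed - eps))
    if exhaustive:
        return b / len(null)            # observed relabeling is among `null`
    return (1 + b) / (1 + len(null))    # add-one estimator, never zero


# ---------------------------------------------------------------------------
# omnibus and post hoc tests
# ---------------------------------------------------------------------------

def permutation_ancova(
    y,
    groups,
    covariates=None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    force_monte_carlo: bool = False,
) -> PermutationResult:
    """Permutation ANCOVA-type omnibus F test for a group factor.

    The observed F tests equality of group means adjusted for covariates;
    its permutation p-value comes from the Freedman-Lane scheme.  With no
    covariates and few enough distinct relabelings, the null is enumerated
    exhaustively.
    """
    y = np.asarray(y, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = np.asarray(groups)
    X, Z, levels = build_design(groups, covariates)
    df1 = len(levels) - 1
    df2 = len(y) - X.shape[1]
    if df2 <= 0:
        raise DesignError("no residual degrees of freedom")
    Rx, Rz = _residual_maker(X), _residual_maker(Z)

    F_obs = float(_f_stats(y[None, :], Rx, Rz, df1, df2)[0])
    perms, exhaustive = _permutation_plan(
        groups, levels, covariates is not None, n_perm, seed, force_monte_carlo
    )
    Y = _freedman_lane_responses(y, Z, perms)
    F_null = _f_stats(Y, Rx, Rz, df1, df2)
    p = _perm_pvalue(F_obs, F_null, exhaustive)
    return PermutationResult(
        statistic_name="F", observed=F_obs, p_value=p, n_perm=len(perms),
        seed=seed, tail="two", contrast="group omnibus (" + "/".join(levels) + ")",
        df=(float(df1), float(df2)), exhaustive=exhaustive,
    )


def pairwise_contrasts(levels: list[str]) -> list[tuple[str, str, str]]:
    """The six one-tailed contrasts (A>B and A<B per unordered pair)."""
    out = []
    for a, b in itertools.combinations(levels, 2):
        out.append((a, b, ">"))
        out.append((a, b, "<"))
    return out


def posthoc_pairwise(
    y,
    groups,
    covariates=None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    n_tests: int | None = None,
    force_monte_carlo: bool = False,
) -> list[PermutationResult]:
    """One-tailed pairwise group contrasts with Bonferroni FWER adjustment.

    All contrasts share a single set of Freedman-Lane permutations.  The
    family-wise adjusted p-value is ``min(1, p * n_tests)`` (``n_tests``
    defaults to the number of contrasts, six for three groups), equivalent
    to testing each unadjusted p against alpha / n_tests.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    X, Z, levels = build_design(groups, covariates)
    df2 = len(y) - X.shape[1]
    if df2 <= 0:
        raise DesignError("no residual degrees of freedom")
    Rx = _residual_maker(X)
    contrasts = pairwise_contrasts(levels)
    if n_tests is None:
        n_tests = len(contrasts)

    perms, exhaustive = _permutation_plan(
        groups, levels, covariates is not None, n_perm, seed, force_monte_carlo
    )
    Y = _freedman_lane_responses(y, Z, perms)

    results: list[PermutationResult] = []
    for a, b, direction in contrasts:
        c = np.zeros(X.shape[1])
        c[levels.index(a)], c[levels.index(b)] = 1.0, -1.0
        if direction == "<":
            c = -c
        t_obs = float(_t_stats(y[None, :], X, c, Rx, df2)[0])
        t_null = _t_stats(Y, X, c, Rx, df2)
        p = _perm_pvalue(t_obs, t_null, exhaustive)
        results.append(PermutationResult(
            statistic_name="t", observed=t_obs, p_value=p, n_perm=len(perms),
            seed=seed, tail="one", contrast=f"{a}{direction}{b}", df=float(df2),
            p_fwer=min(1.0, p * n_tests), exhaustive=exhaustive,
        ))
    return results


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str          # "exact" or "t-approx"
    flag: str = ""


def spearman_corr(x, y, exact_max_n: int = 10) -> SpearmanResult:
    """Tie-aware Spearman rank correlation.

    rho is the Pearson correlation of mid-ranks.  The p-value (two-sided)
    is exact — computed over all n! rank permutations — for ``n <=
    exact_max_n``, and uses the t approximation ``t = rho *
    sqrt((n-2)/(1-rho^2))`` on ``n - 2`` degrees of freedom otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return SpearmanResult(rho=float("nan"), p_value=float("nan"), n=n,
                              method="undefined", flag="constant-input")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = float(np.linalg.norm(rxc) * np.linalg.norm(ryc))
    rho = float(rxc @ ryc) / denom

    if n <= exact_max_n:
        rx_hat = rxc / np.linalg.norm(rxc)
        ry_hat = ryc / np.linalg.norm(ryc)
        total = math.factorial(n)
        count = 0
        eps = 1e-12
        chunk: list[tuple[int, ...]] = []
        it = itertools.permutations(range(n))
        while True:
            chunk = list(itertools.islice(it, 200_000))
            if not chunk:
                break
            rho_perm = ry_hat[np.array(chunk)] @ rx_hat
            count += int(np.sum(np.abs(rho_perm) >= abs(rho) - eps))
        return SpearmanResult(rho=rho, p_value=count / total, n=n, method="exact")

    with np.errstate(divide="ignore"):
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho=rho, p_value=min(p, 1.0), n=n, method="t-approx")


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def levene_test(y, groups) -> tuple[float, float]:
    """Brown-Forsythe (median-centered) Levene test across groups."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    samples = [y[groups == g] for g in sorted(set(groups.tolist()))]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 members each")
    W, p = stats.levene(*samples, center="median")
    return float(W), float(p)


def adjust_moca(raw: int, education_years: int) -> int:
    """Education-adjusted MoCA: +1 point for <= 12 years of education, capped at 30."""
    if not 0 <= raw <= 30:
        raise ValueError(f"raw MoCA must be in [0, 30], got {raw}")
    adjusted = raw + 1 if education_years <= 12 else raw
    return int(min(adjusted, 30))


def _median_iqr(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1), "n": int(len(values))}


def descriptive_tests(
    table: pd.DataFrame,
    group_col: str = "group",
    age_col: str = "age",
    sex_col: str = "sex",
    clinical_cols: list[str] | None = None,
    pairwise_groups: tuple[str, str] = ("MSA", "PD"),
) -> dict:
    """Demographic and clinical descriptives across groups.

    Kruskal-Wallis for age, chi-square (no continuity correction) for the
    sex-by-group table, two-sided Mann-Whitney U between the two patient
    groups for clinical scores, and median/IQR summaries throughout.
    """
    for col in (group_col, age_col, sex_col):
        if col not in table.columns:
            raise SchemaError(f"covariate table is missing required column '{col}'")
    groups = sorted(table[group_col].unique().tolist())
    report: dict = {"groups": groups, "summaries": {}, "tests": {}}

    age_samples = [table.loc[table[group_col] == g, age_col].to_numpy(float) for g in groups]
    if np.ptp(np.concatenate(age_samples)) == 0:
        H, p_age = 0.0, 1.0   # identical distributions; Kruskal-Wallis undefined
    else:
        H, p_age = stats.kruskal(*age_samples)
    report["tests"]["age_kruskal"] = {"H": float(H), "p": float(p_age)}

    sex_table = pd.crosstab(table[sex_col], table[group_col])
    chi2, p_sex, dof, _ = stats.chi2_contingency(sex_table.to_numpy(), correction=False)
    report["tests"]["sex_chi2"] = {"chi2": float(chi2), "p": float(p_sex), "dof": int(dof)}

    if clinical_cols is None:
        clinical_cols = [c for c in ("moca_raw", "moca_adjusted") if c in table.columns]
    a, b = pairwise_groups
    for col in clinical_cols:
        if col not in table.columns:
            raise SchemaError(f"covariate table is missing clinical column '{col}'")
        xa = table.loc[table[group_col] == a, col].dropna().to_numpy(float)
        xb = table.loc[table[group_col] == b, col].dropna().to_numpy(float)
        if len(xa) and len(xb):
            U, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            report["tests"][f"{col}_mannwhitney_{a}_vs_{b}"] = {"U": float(U), "p": float(p)}

    numeric = [age_col] + clinical_cols
    for g in groups:
        sub = table[table[group_col] == g]
        report["summaries"][g] = {
            col: _median_iqr(sub[col].dropna().to_numpy(float))
            for col in numeric if col in sub.columns and sub[col].notna().any()
        }
        report["summaries"][g][sex_col] = sub[sex_col].value_counts().to_dict()
    return report
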