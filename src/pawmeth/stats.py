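"""The cohort-level statistical battery for the global-methylation stage.

Covers the tests applied to the 19-dog cohort: Lilliefors-corrected
Kolmogorov-Smirnov normality, pooled-variance Student t (raw vectors or
published summary triples), Pearson and Spearman correlation, exact
Mann-Whitney, and additive two-factor ANOVA with Type-II sums of squares.

Every test returns a :class:`TestResult` so downstream reporting is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    estimate: float | None = None   # r, rho, mean difference ... where natural
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if np.any(~np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


# ------------------------------------------------------------------ normality

def ks_normality(values) -> TestResult:
    """Kolmogorov-Smirnov normality test with parameters estimated from data.

    Because the null mean and SD are the sample estimates, the plain KS null
    distribution is wrong; the Lilliefors correction is used for the p-value.
    """
    v = _as_vector(values, "values")
    if v.size < 4:
        raise ValueError("normality test needs n >= 4")
    if np.ptp(v) == 0:
        raise ValueError("constant input: normality is undefined")
    d, p = lilliefors(v, dist="norm", pvalmethod="table")
    return TestResult("ks_normality", float(d), float(p), df=v.size)


def ks_statistic(values) -> float:
    """The raw one-sample KS distance to a normal fit (no p-value)."""
    v = _as_vector(values, "values")
    return float(sps.kstest(v, "norm", args=(v.mean(), v.std(ddof=1))).statistic)


# -------------------------------------------------------------------- t-tests

def t_test_pooled(
    a=None,
    b=None,
    *,
    summary_a: tuple[int, float, float] | None = None,
    summary_b: tuple[int, float, float] | None = None,
    equal_var: bool = True,
) -> TestResult:
    """Two-sided two-sample t-test from raw vectors or summary triples.

    Summaries are ``(n, mean, sd)`` with the sample (ddof=1) SD. The pooled
    (Student) form is the default; ``equal_var=False`` gives Welch. Raw and
    summary inputs of the same data agree to machine precision.
    """
    if summary_a is not None or summary_b is not None:
        if summary_a is None or summary_b is None:
            raise ValueError("both summaries are required")
        n1, m1, s1 = summary_a
        n2, m2, s2 = summary_b
    else:
        va, vb = _as_vector(a, "a"), _as_vector(b, "b")
        if va.size < 2 or vb.size < 2:
            raise ValueError("each group needs n >= 2")
        n1, m1, s1 = va.size, va.mean(), va.std(ddof=1)
        n2, m2, s2 = vb.size, vb.mean(), vb.std(ddof=1)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(
        "t_pooled" if equal_var else "t_welch",
        float(res.statistic),
        float(res.pvalue),
        df=df,
        estimate=float(m1 - m2),
    )


# --------------------------------------------------------------- correlations

def pearson(x, y) -> TestResult:
    vx, vy = _as_vector(x, "x"), _as_vector(y, "y")
    if vx.size != vy.size or vx.size < 3:
        raise ValueError("paired vectors of equal length n >= 3 required")
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = sps.pearsonr(vx, vy)
    return TestResult("pearson", float(res.statistic), float(res.pvalue),
                      df=vx.size - 2, estimate=float(res.statistic))


def spearman(x, y) -> TestResult:
    """Pearson correlation of mid-ranks (average ranks on ties)."""
    vx, vy = _as_vector(x, "x"), _as_vector(y, "y")
    if vx.size != vy.size or vx.size < 3:
        raise ValueError("paired vectors of equal length n >= 3 required")
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = sps.spearmanr(vx, vy)
    return TestResult("spearman", float(res.statistic), float(res.pvalue),
                      df=vx.size - 2, estimate=float(res.statistic))


# --------------------------------------------------------------- Mann-Whitney

def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of the exact null distribution of U1 over all C(n1+n2, n1) labelings.

    Dynamic-programming recurrence over the Gaussian binomial coefficient:
    f[n1][u] after processing each of the n2 'other' observations. Equivalent
    to full enumeration of labelings, feasible for moderate n.
    """
    max_u = n1 * n2
    # c[u] = number of rank arrangements giving U1 = u
    c = np.zeros(max_u + 1, dtype=float)
    c[0] = 1.0
    # standard recurrence: product generating function prod_{i=1..n1} (1-q^{n2+i})/(1-q^i)
    for i in range(1, n1 + 1):
        # multiply by (1 - q^(n2+i)), divide by (1 - q^i), done via cumulative sums
        nxt = np.zeros_like(c)
        for u in range(max_u + 1):
            nxt[u] = c[u]
            if u >= i:
                nxt[u] += nxt[u - i]
            if u >= n2 + i:
                nxt[u] -= c[u - (n2 + i)]
        c = nxt
    return c


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test; U is reported as min(U1, U2).

    ``mode='exact'`` enumerates the full null distribution of U (valid
    without ties); ``mode='normal'`` uses the tie-corrected normal
    approximation; ``mode='auto'`` picks exact when n1*n2 <= 400 and the
    data are tie-free.
    """
    vx, vy = _as_vector(x, "x"), _as_vector(y, "y")
    n1, n2 = vx.size, vy.size
    if n1 < 1 or n2 < 1:
        raise ValueError("each group needs n >= 1")
    pooled = np.concatenate([vx, vy])
    has_ties = np.unique(pooled).size < pooled.size
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    if mode == "auto":
        mode = "exact" if (n1 * n2 <= 400 and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact enumeration requires tie-free data")
        counts = _u_null_counts(n1, n2)
        total = comb(n1 + n2, n1)
        # two-sided: both tails at distance >= |u - mean| from the mean,
        # which by symmetry is 2 * P(U <= min(U1, U2))
        p = 2.0 * counts[: int(u) + 1].sum() / total
        p = min(p, 1.0)
    elif mode == "normal":
        res = sps.mannwhitneyu(vx, vy, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult("mann_whitney", float(u), float(p),
                      extra={"U1": float(u1), "U2": float(u2), "mode": mode})


# ---------------------------------------------------------------------- ANOVA

def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> pd.DataFrame:
    """Additive (no-interaction) two-factor ANOVA, Type-II sums of squares.

    Returns one row per factor with F, numerator/denominator df and p.
    Designed for unbalanced designs where main effects are reported; a
    rank-deficient (aliased) design raises an error naming the factor.
    """
    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    for fac in (factor_a, factor_b):
        if data[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")
    formula = f"Q('{response}') ~ C(Q('{factor_a}')) + C(Q('{factor_b}'))"
    fit = ols(formula, data=data).fit()
    if fit.model.exog.shape[1] > np.linalg.matrix_rank(fit.model.exog):
        raise ValueError(
            f"rank-deficient design: {factor_a!r} is aliased with {factor_b!r}"
        )
    table = anova_lm(fit, typ=2)
    out = []
    resid_df = float(table.loc["Residual", "df"])
    for fac, row_label in ((factor_a, f"C(Q('{factor_a}'))"), (factor_b, f"C(Q('{factor_b}'))")):
        row = table.loc[row_label]
        out.append(
            {
                "factor": fac,
                "sum_sq": float(row["sum_sq"]),
                "df": float(row["df"]),
                "resid_df": resid_df,
                "F": float(row["F"]),
                "p_value": float(row["PR(>F)"]),
            }
        )
    return pd.DataFrame(out)
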