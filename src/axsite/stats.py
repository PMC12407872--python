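"""Statistical layer: t-tests, multiplicity corrections, two-way ANOVA, volcano filter.

Conventions: all tests are two-sided.  The individual-vs-group comparison
(one subject's stimulations against a pooled control group) is a Welch
t-test with Satterthwaite degrees of freedom, Bonferroni-corrected by the
number of subjects compared; group-level comparisons use the pooled-variance
two-sample t-test.  The two-way ANOVA uses Type III sums of squares with
sum-to-zero coding, which coincides with the classical balanced
decomposition, and offers Sidak-adjusted pairwise cell comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "VolcanoResult",
    "t_test",
    "adjust_pvalues",
    "per_comparison_alpha",
    "two_way_anova",
    "individual_vs_group",
    "volcano_filter",
]


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    method: str
    p_adjusted: float | None = None


@dataclass
class VolcanoResult:
    table: pd.DataFrame
    fold_change_bound: float  # linear fold change at |log2fc| = fc_min


def t_test(a, b, variant: str = "pooled") -> TestResult:
    """Two-sided two-sample t-test.

    ``variant='pooled'`` assumes equal variances (df = n1+n2-2);
    ``variant='welch'`` uses the Welch statistic with Satterthwaite df.
    Two zero-variance groups with equal means give t=0, p=1 by convention;
    zero variance with unequal means is degenerate and rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return TestResult(0.0, float(df), 1.0, variant)
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), variant)


def adjust_pvalues(ps, method: str = "bonferroni", m: int | None = None) -> np.ndarray:
    """Family-wise adjustment: Bonferroni min(1, m*p) or Sidak 1-(1-p)^m."""
    ps = np.asarray(ps, dtype=float)
    if np.any((ps < 0) | (ps > 1) | ~np.isfinite(ps)):
        raise ValueError("p values must be in [0, 1]")
    if m is None:
        m = max(ps.size, 1)
    if m < max(ps.size, 1):
        raise ValueError("m must be at least the number of p values")
    if method == "bonferroni":
        return np.minimum(1.0, m * ps)
    if method == "sidak":
        return 1.0 - (1.0 - ps) ** m
    raise ValueError("method must be 'bonferroni' or 'sidak'")


def per_comparison_alpha(alpha: float, m: int, method: str = "bonferroni") -> float:
    """Per-comparison significance level for family-wise ``alpha`` over m comparisons."""
    if not 0 < alpha < 1 or m < 1:
        raise ValueError("alpha must be in (0,1) and m >= 1")
    if method == "bonferroni":
        return alpha / m
    if method == "sidak":
        return 1.0 - (1.0 - alpha) ** (1.0 / m)
    raise ValueError("method must be 'bonferroni' or 'sidak'")


def individual_vs_group(individual, group, n_individuals: int) -> TestResult:
    """Welch t-test of one subject's measurements against a pooled control group,
    Bonferroni-corrected by the number of subjects compared."""
    res = t_test(individual, group, variant="welch")
    res.p_adjusted = float(adjust_pvalues([res.p], "bonferroni", m=n_individuals)[0])
    return res


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------


def _sum_code(levels: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Sum-to-zero contrast columns (k-1) for one factor."""
    k = len(levels)
    cols = np.zeros((values.size, k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[values == lev, j] = 1.0
    cols[values == levels[-1], :] = -1.0
    return cols


def _ss_residual(y: np.ndarray, x: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    posthoc: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Fixed-effects two-way ANOVA, Type III SS with sum-to-zero coding.

    Requires >= 2 levels per factor and >= 2 replicates in every cell (the
    interaction is included).  Returns the ANOVA table (rows: factor_a,
    factor_b, interaction, residual; columns: sum_sq, df, F, p) and, when
    ``posthoc`` is set, Sidak-adjusted pairwise comparisons of ``factor_b``
    levels within each level of ``factor_a`` using the pooled error term.
    With zero residual *and* zero effect variation (all observations equal),
    F is undefined and p is reported as 1.
    """
    y = data[response].to_numpy(dtype=float)
    fa = data[factor_a].to_numpy()
    fb = data[factor_b].to_numpy()
    la = np.unique(fa)
    lb = np.unique(fb)
    if la.size < 2 or lb.size < 2:
        raise ValueError("each factor needs at least 2 levels")
    for a, b in itertools.product(la, lb):
        n_cell = int(np.sum((fa == a) & (fb == b)))
        if n_cell == 0:
            raise ValueError(f"empty cell: {factor_a}={a!r}, {factor_b}={b!r}")
        if n_cell < 2:
            raise ValueError(
                f"cell {factor_a}={a!r}, {factor_b}={b!r} has < 2 replicates"
            )

    xa = _sum_code(la, fa)
    xb = _sum_code(lb, fb)
    xab = np.column_stack([xa[:, i] * xb[:, j] for i in range(xa.shape[1]) for j in range(xb.shape[1])])
    intercept = np.ones((y.size, 1))
    x_full = np.column_stack([intercept, xa, xb, xab])

    sse_full = _ss_residual(y, x_full)
    df_err = y.size - x_full.shape[1]
    ss_total = float(((y - y.mean()) ** 2).sum())
    eps = 1e-12 * max(ss_total, 1.0)  # numerically-zero scale for lstsq residuals
    blocks = {
        factor_a: np.column_stack([intercept, xb, xab]),
        factor_b: np.column_stack([intercept, xa, xab]),
        "interaction": np.column_stack([intercept, xa, xb]),
    }
    dfs = {factor_a: la.size - 1, factor_b: lb.size - 1, "interaction": (la.size - 1) * (lb.size - 1)}

    degenerate = df_err <= 0 or sse_full <= eps
    mse = sse_full / df_err if not degenerate else np.nan
    rows = []
    for name, x_red in blocks.items():
        ss = max(_ss_residual(y, x_red) - sse_full, 0.0)
        df = dfs[name]
        if not degenerate:
            f_stat = (ss / df) / mse
            p = float(sps.f.sf(f_stat, df, df_err))
        else:
            # no residual variance: any nonzero effect is exact, all-equal data is p=1
            f_stat = np.nan
            p = 0.0 if ss > eps else 1.0
        rows.append({"effect": name, "sum_sq": ss, "df": df, "F": f_stat, "p": p})
    rows.append({"effect": "residual", "sum_sq": sse_full, "df": df_err, "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows).set_index("effect")

    ph = None
    if posthoc:
        comps = []
        pairs = list(itertools.combinations(lb, 2))
        m = la.size * len(pairs)
        for a in la:
            for b1, b2 in pairs:
                g1 = y[(fa == a) & (fb == b1)]
                g2 = y[(fa == a) & (fb == b2)]
                diff = g1.mean() - g2.mean()
                if not degenerate:
                    se = np.sqrt(mse * (1.0 / g1.size + 1.0 / g2.size))
                    t = diff / se
                    p = float(2 * sps.t.sf(abs(t), df_err))
                else:
                    t = np.nan
                    p = 0.0 if abs(diff) > 1e-12 else 1.0
                comps.append(
                    {
                        factor_a: a,
                        "level_1": b1,
                        "level_2": b2,
                        "diff": diff,
                        "t": t,
                        "p": p,
                    }
                )
        ph = pd.DataFrame(comps)
        ph["p_sidak"] = adjust_pvalues(ph["p"].to_numpy(), "sidak", m=m)
    return table, ph


# ---------------------------------------------------------------------------
# volcano filter
# ---------------------------------------------------------------------------


def volcano_filter(
    table: pd.DataFrame,
    p_max: float = 0.05,
    fc_min: float = 0.58,
    p_col: str = "p",
    fc_col: str = "log2fc",
) -> VolcanoResult:
    """Flag features with unadjusted p < p_max and |log2 fold change| > fc_min.

    The default |log2FC| bound of 0.58 corresponds to a linear fold change
    of 2**0.58 ~ 1.5, reported alongside the flagged table.
    """
    out = table.copy()
    if len(out):
        vals = out[[p_col, fc_col]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("p values and log2 fold changes must be finite")
        out["significant"] = (out[p_col] < p_max) & (out[fc_col].abs() > fc_min)
    else:
        out["significant"] = pd.Series(dtype=bool)
    return VolcanoResult(table=out, fold_change_bound=float(2.0**fc_min))
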