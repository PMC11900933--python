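"""Rank-based two-group statistics for case-control cohort tables.

Continuous variables are summarised as median [25th; 75th percentile]
(type-7, linear-interpolation quantiles) and compared between the two
independent groups with the two-sided Mann-Whitney rank-sum test:
exact null distribution when the pooled sample is small (<= 20) and
tie-free, otherwise the normal approximation with tie-variance and
continuity corrections.  Categorical variables are compared with the
Pearson chi-squared test (no Yates correction by default).  Monotone
association is measured with Spearman's rank correlation (mid-ranks
for ties; exact permutation p-value at n <= 8, t approximation
otherwise).  A Wilcoxon signed-rank test is provided separately for
genuinely paired measurements; it is not a two-independent-group test.

p-values are displayed as 'ns' (>= 0.05), '=0.0xx', or '<0.001'.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "SpearmanResult",
    "summarize_group",
    "rank_sum_test",
    "signed_rank_test",
    "chi_squared_test",
    "spearman_correlation",
    "format_p",
    "build_table1",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group comparison: per-group median and quartiles (continuous
    variables only), the test statistic, and the two-sided p-value."""

    name: str
    statistic: float
    p_value: float
    test_name: str
    median_a: float | None = None
    q25_a: float | None = None
    q75_a: float | None = None
    median_b: float | None = None
    q25_b: float | None = None
    q75_b: float | None = None
    n_a: int = 0
    n_b: int = 0

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    n: int = 0
    method: str = ""


def format_p(p: float) -> str:
    """Render a p-value the way clinical tables print them."""
    if math.isnan(p):
        return "na"
    if p >= 0.05:
        return "ns"
    if p < 0.001:
        return "<0.001"
    return f"={p:.3f}"


def summarize_group(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q25, q75) with type-7 linear-interpolation quantiles."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot summarise an empty group")
    q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75])  # type 7 by default
    return float(med), float(q25), float(q75)


def _clean(values: Sequence[float], label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError(f"group {label} needs >= 2 non-missing values")
    return arr


def rank_sum_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    name: str = "",
) -> ComparisonResult:
    """Two-sided Mann-Whitney rank-sum test between independent groups.

    The exact null distribution of U is used when n_a + n_b <= 20 and
    the pooled sample has no ties; otherwise the normal approximation
    with mid-ranks, tie-variance correction and continuity correction.
    """
    a = _clean(values_a, "A")
    b = _clean(values_b, "B")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size <= 20) and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic")
    med_a, q25_a, q75_a = summarize_group(a)
    med_b, q25_b, q75_b = summarize_group(b)
    return ComparisonResult(
        name=name, statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        test_name="mann-whitney-exact" if exact else "mann-whitney-normal",
        median_a=med_a, q25_a=q25_a, q75_a=q75_a,
        median_b=med_b, q25_b=q25_b, q75_b=q75_b,
        n_a=int(a.size), n_b=int(b.size))


def signed_rank_test(
    values_pre: Sequence[float],
    values_post: Sequence[float],
    name: str = "",
) -> ComparisonResult:
    """Wilcoxon signed-rank test for paired measurements (equal length).

    Kept distinct from :func:`rank_sum_test`: pairing is a design
    property, and the signed-rank test is undefined for two independent
    groups of unequal size.
    """
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[keep], post[keep]
    if pre.size < 2:
        raise ValueError("need >= 2 complete pairs")
    res = stats.wilcoxon(pre, post, alternative="two-sided")
    med_a, q25_a, q75_a = summarize_group(pre)
    med_b, q25_b, q75_b = summarize_group(post)
    return ComparisonResult(
        name=name, statistic=float(res.statistic), p_value=float(res.pvalue),
        test_name="wilcoxon-signed-rank",
        median_a=med_a, q25_a=q25_a, q75_a=q75_a,
        median_b=med_b, q25_b=q25_b, q75_b=q75_b,
        n_a=int(pre.size), n_b=int(post.size))


def chi_squared_test(
    table: Sequence[Sequence[float]] | np.ndarray,
    name: str = "",
    yates: bool = False,
) -> ComparisonResult:
    """Pearson chi-squared test of independence on an r x c count table.

    No Yates continuity correction unless requested.  Warns when any
    expected count falls below 5 (the classical validity rule of thumb).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise ValueError("contingency table has a zero marginal")
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=yates)
    if (expected < 5).any():
        warnings.warn(
            f"{name or 'contingency table'}: expected count < 5; "
            "chi-squared approximation may be poor", stacklevel=2)
    return ComparisonResult(
        name=name, statistic=float(chi2), p_value=float(p),
        test_name="chi-squared" + ("-yates" if yates else ""),
        n_a=int(counts[0].sum()), n_b=int(counts[1].sum()))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p: enumerate all n! pairings of the ranks."""
    perms = np.array(list(itertools.permutations(ry)))
    rx_c = rx - rx.mean()
    perms_c = perms - ry.mean()  # every permutation has the same mean
    denom = math.sqrt(float((rx_c ** 2).sum() * ((ry - ry.mean()) ** 2).sum()))
    rhos = perms_c @ rx_c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_correlation(
    x: Sequence[float],
    y: Sequence[float],
    exact_n_max: int = 8,
) -> SpearmanResult:
    """Spearman's rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks.  For n <= exact_n_max
    the p-value is the exact permutation tail (all n! pairings);
    otherwise the usual t approximation on n - 2 degrees of freedom.
    Constant input yields rho = nan with a warning.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = xa.size
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    rx = stats.rankdata(xa)  # mid-ranks for ties
    ry = stats.rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return SpearmanResult(math.nan, math.nan, n, "undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_n_max:
        return SpearmanResult(rho, _exact_spearman_p(rx, ry, rho), n, "exact")
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, n, "t-approx")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return SpearmanResult(rho, float(min(p, 1.0)), n, "t-approx")


def _is_categorical(series: pd.Series) -> bool:
    if series.dtype == bool or series.dtype == object:
        return True
    vals = set(series.dropna().unique())
    return vals <= {0, 1, 0.0, 1.0, True, False}


def build_table1(
    cohort: pd.DataFrame,
    group_col: str = "group",
    variables: Sequence[str] | None = None,
    categorical: Sequence[str] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-variable group-summary table for a two-group cohort.

    Continuous variables get median [q25; q75] per group and a rank-sum
    p; categorical variables get per-level counts and a chi-squared p.
    With ``fdr=True`` a Benjamini-Hochberg adjusted p column is added
    (off by default: each comparison is reported at its raw level).
    Variables with fewer than 2 non-missing subjects in a group are
    skipped with a warning.
    """
    if group_col not in cohort.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = [g for g in cohort[group_col].unique() if pd.notna(g)]
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    ga, gb = sorted(groups, key=str)
    sub_a = cohort[cohort[group_col] == ga]
    sub_b = cohort[cohort[group_col] == gb]

    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in (group_col, "sample_id")]
    cat_set = (set(categorical) if categorical is not None
               else {v for v in variables if _is_categorical(cohort[v])})

    rows = []
    for var in variables:
        col_a = sub_a[var].dropna()
        col_b = sub_b[var].dropna()
        if col_a.empty and col_b.empty:
            warnings.warn(f"{var}: empty in both groups, skipped", stacklevel=2)
            continue
        try:
            if var in cat_set:
                levels = sorted(pd.concat([col_a, col_b]).unique(), key=str,
                                reverse=True)
                counts = [[int((col == lv).sum()) for lv in levels]
                          for col in (col_a, col_b)]
                res = chi_squared_test(counts, name=var)
                summ_a = "/".join(str(c) for c in counts[0])
                summ_b = "/".join(str(c) for c in counts[1])
                levels_str = "/".join(str(lv) for lv in levels)
                label = f"{var} ({levels_str})"
            else:
                res = rank_sum_test(col_a, col_b, name=var)
                summ_a = f"{res.median_a:.1f} [{res.q25_a:.1f}; {res.q75_a:.1f}]"
                summ_b = f"{res.median_b:.1f} [{res.q25_b:.1f}; {res.q75_b:.1f}]"
                label = var
        except ValueError as err:
            warnings.warn(f"{var}: skipped ({err})", stacklevel=2)
            continue
        rows.append({
            "parameter": label,
            f"group_{ga}": summ_a,
            f"group_{gb}": summ_b,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "p_display": res.p_display,
            "test": res.test_name,
            "n_a": res.n_a,
            "n_b": res.n_b,
        })
    report = pd.DataFrame(rows)
    if fdr and not report.empty:
        from statsmodels.stats.multitest import multipletests
        report["p_bh"] = multipletests(report["p_value"], method="fdr_bh")[1]
    return report
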