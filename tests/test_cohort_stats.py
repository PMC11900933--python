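"""Tests for the rank-based group-comparison layer.

Exact p-values are validated against brute-force enumeration oracles:
all C(n, n_a) rank assignments for the rank-sum test, all n!
permutations for Spearman.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata, spearmanr

from epiaging.cohort_stats import (
    build_table1,
    chi_squared_test,
    format_p,
    rank_sum_test,
    signed_rank_test,
    spearman_correlation,
    summarize_group,
)


def brute_force_ranksum_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating every assignment
    of the pooled ranks to group A (tie-free samples only)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = len(a)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = np.array([
        ranks[list(idx)].sum() - na * (na + 1) / 2
        for idx in itertools.combinations(range(len(pooled)), na)])
    p = 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean())
    return min(p, 1.0)


def brute_force_spearman_p(x, y):
    """Two-sided permutation p using an independent rho (scipy's)."""
    rho_obs = spearmanr(x, y).statistic
    y = np.asarray(y, float)
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        rho = spearmanr(x, perm).statistic
        count += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_small_sample_exact_p(self):
        # U = 0; all 6 rank assignments enumerable by hand: p = 2/6
        res = rank_sum_test([1, 2], [10, 11])
        assert res.test_name == "mann-whitney-exact"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_exact_p_matches_full_enumeration_at_8_vs_8(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=8)
        res = rank_sum_test(a, b)
        assert res.test_name == "mann-whitney-exact"
        assert res.p_value == pytest.approx(brute_force_ranksum_p(a, b),
                                            abs=1e-12)

    @pytest.mark.parametrize("trial", range(40))
    def test_exact_p_matches_enumeration_random_small_splits(self, trial):
        rng = np.random.default_rng(1000 + trial)
        na = int(rng.integers(2, 11))
        nb = int(rng.integers(2, 13 - na))
        a, b = rng.uniform(size=na), rng.uniform(size=nb)
        res = rank_sum_test(a, b)
        assert res.p_value == pytest.approx(brute_force_ranksum_p(a, b),
                                            abs=1e-12)

    def test_tied_or_large_samples_use_corrected_normal_approximation(self):
        res = rank_sum_test([1, 1, 2, 3], [2, 2, 3, 4])
        assert res.test_name == "mann-whitney-normal"
        rng = np.random.default_rng(0)
        res = rank_sum_test(rng.normal(size=15), rng.normal(size=15))
        assert res.test_name == "mann-whitney-normal"

    def test_quartiles_filled_per_group(self):
        res = rank_sum_test([1, 2, 3, 4, 5], [10, 20, 30, 40])
        assert (res.median_a, res.q25_a, res.q75_a) == (3, 2, 4)
        assert res.median_b == pytest.approx(25.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1, 2])


class TestSignedRank:
    def test_paired_shift_detected(self):
        pre = np.arange(1, 16, dtype=float)
        res = signed_rank_test(pre, pre + 2.0)
        assert res.p_value < 0.01

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            signed_rank_test([1, 2, 3], [1, 2])


class TestChiSquared:
    def test_perfect_independence(self):
        res = chi_squared_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_sex_split_similar_groups_not_significant(self):
        # 19/17 vs 11/13 female/male split between groups
        res = chi_squared_test([[19, 17], [11, 13]])
        assert res.statistic < 1.0
        assert res.p_display == "ns"

    def test_matches_closed_form_2x2(self):
        a, b, c, d = 12, 5, 7, 9
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        res = chi_squared_test([[a, b], [c, d]])
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_row_and_column_permutation_invariance(self):
        table = np.array([[12, 5, 3], [7, 9, 8]])
        base = chi_squared_test(table).statistic
        assert chi_squared_test(table[::-1]).statistic == pytest.approx(base)
        assert chi_squared_test(table[:, ::-1]).statistic == pytest.approx(base)

    def test_low_expected_count_warns(self):
        with pytest.warns(UserWarning, match="expected count"):
            chi_squared_test([[1, 9], [2, 8]])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared_test([[0, 5], [0, 7]])


class TestSpearman:
    def test_monotone_identity(self):
        x = [1, 2, 5, 8, 9, 12]
        assert spearman_correlation(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman_correlation(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_tied_dataset_matches_hand_midrank_computation(self):
        # mid-ranks of x: 1, 2.5, 2.5, 4, 5, 6; of y: 2, 1, 3.5, 3.5, 6, 5
        res = spearman_correlation([1, 2, 2, 3, 4, 5], [2, 1, 3, 3, 5, 4])
        assert res.rho == pytest.approx(0.8088235294117647, abs=1e-12)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(
            brute_force_spearman_p([1, 2, 2, 3, 4, 5], [2, 1, 3, 3, 5, 4]),
            abs=1e-12)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_permutation_oracle(self, n):
        rng = np.random.default_rng(n)
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = spearman_correlation(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_spearman_p(x, y),
                                            abs=1e-12)

    def test_t_approximation_agrees_with_scipy_at_larger_n(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman_correlation(x, y)
        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=40)
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = spearman_correlation(x, y).rho
        assert spearman_correlation(np.exp(x), y).rho == pytest.approx(base)
        assert spearman_correlation(x, 3 * y + 7).rho == pytest.approx(base)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.rho)


class TestSummaries:
    @pytest.mark.parametrize("values, expected", [
        ([1, 2, 3, 4, 5], (3, 2, 4)),
        ([1, 2, 3, 4], (2.5, 1.75, 3.25)),
        ([7.0], (7.0, 7.0, 7.0)),
    ])
    def test_type7_quantiles(self, values, expected):
        assert summarize_group(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([])

    @given(values=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_quartile_ordering(self, values):
        med, q25, q75 = summarize_group(values)
        assert q25 <= med <= q75

    @pytest.mark.parametrize("p, display", [
        (0.2, "ns"), (0.05, "ns"), (0.049, "=0.049"), (0.0021, "=0.002"),
        (0.0009, "<0.001"), (float("nan"), "na"),
    ])
    def test_p_display_rules(self, p, display):
        assert format_p(p) == display


class TestTable1:
    def _cohort(self, rng, shift=0.0):
        n = 30
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(2 * n)],
            "group": ["A"] * n + ["B"] * n,
            "weight": np.r_[rng.normal(100, 10, n), rng.normal(100 + shift, 10, n)],
            "smoker": rng.integers(0, 2, 2 * n),
        })

    def test_large_injected_shift_flagged_below_0_001(self):
        report = build_table1(self._cohort(np.random.default_rng(1), shift=30))
        row = report[report.parameter == "weight"].iloc[0]
        assert row.p_display == "<0.001"

    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(2)
        half = pd.DataFrame({
            "sample_id": [f"a{i}" for i in range(20)],
            "group": "A",
            "weight": rng.normal(100, 10, 20)})
        other = half.assign(group="B", sample_id=[f"b{i}" for i in range(20)])
        report = build_table1(pd.concat([half, other], ignore_index=True))
        assert report[report.parameter == "weight"].iloc[0].p_value > 0.95

    def test_empty_column_skipped_with_warning(self):
        df = self._cohort(np.random.default_rng(3))
        df["missing_var"] = np.nan
        with pytest.warns(UserWarning, match="missing_var"):
            report = build_table1(df)
        assert not report.parameter.str.contains("missing_var").any()

    def test_categorical_column_uses_chi_squared(self):
        report = build_table1(self._cohort(np.random.default_rng(4)))
        row = report[report.parameter.str.startswith("smoker")].iloc[0]
        assert row.test.startswith("chi-squared")

    def test_fdr_option_appends_adjusted_column(self):
        report = build_table1(self._cohort(np.random.default_rng(5)), fdr=True)
        assert "p_bh" in report.columns
        assert (report.p_bh >= report.p_value - 1e-12).all()
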