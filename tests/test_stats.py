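"""Nonparametric tests against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tlsquant import (
    bh_adjust,
    fisher_exact_2x2,
    kruskal_wallis,
    run_comparisons,
    wilcoxon_rank_sum,
)
from tlsquant.stats import Comparison, ComparisonPlan

from oracles import (
    bh_step_up,
    fisher_two_sided,
    kruskal_permutation_p,
    wilcoxon_exact_two_sided,
)


class TestWilcoxon:
    def test_separated_triples_exact_p(self):
        # all C(6,3)=20 rank splits; the observed split is one of the two
        # extremes -> two-sided p = 2/20 = 0.1
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_exact_path_matches_enumeration(self):
        """Exact p equals full permutation enumeration for all tie-free
        splits with n_x + n_y <= 10."""
        rng = np.random.default_rng(0)
        for nx in range(1, 6):
            for ny in range(nx, 10 - nx + 1):
                pooled = rng.normal(size=nx + ny)
                while len(np.unique(pooled)) < len(pooled):  # pragma: no cover
                    pooled = rng.normal(size=nx + ny)
                x, y = pooled[:nx], pooled[nx:]
                _, p = wilcoxon_rank_sum(x, y)
                assert p == pytest.approx(wilcoxon_exact_two_sided(x, y), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n12(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(loc=rng.uniform(-1, 1), size=6)
            _, p_exact = wilcoxon_rank_sum(x, y)  # n=12, tie-free -> exact
            res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            diffs.append(abs(p_exact - res.pvalue))
        # continuity-corrected normal approximation tracks the exact law
        assert max(diffs) < 0.02
        assert np.mean(diffs) < 0.01

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestKruskal:
    def test_two_groups_tracks_wilcoxon(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = rng.normal(loc=0.5, size=30)
        _, p_kw = kruskal_wallis([x, y])
        _, p_w = wilcoxon_rank_sum(x, y)
        assert abs(p_kw - p_w) < 0.02

    def test_identical_constant_groups(self):
        with pytest.warns(UserWarning, match="identical"):
            h, p = kruskal_wallis([[3, 3, 3], [3, 3], [3]])
        assert h == 0.0 and p == 1.0

    def test_three_separated_groups_significant(self):
        groups = [[1, 2, 3, 4, 5], [11, 12, 13, 14, 15], [21, 22, 23, 24, 25]]
        h, p = kruskal_wallis(groups)
        assert p < 0.01
        # permutation oracle agrees the configuration is extreme
        assert kruskal_permutation_p(groups, n_perm=20_000, seed=3) < 0.01

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestFisher:
    def test_headline_prevalence_table(self):
        # 16/48 TLS-positive primaries vs 45/55 positive metastases
        assert fisher_exact_2x2([[16, 32], [45, 10]]) < 0.001

    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_diagonal_table_enumeration(self):
        # margins (2,2,2,2): three tables with probabilities 1/6, 4/6, 1/6
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_hypergeometric_enumeration_small_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 9, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                fisher_two_sided(int(a), int(b), int(c), int(d)), abs=1e-9)


class TestBH:
    def test_tail_minimum_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_empty_list(self):
        assert bh_adjust([]) == []

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_matches_step_up_oracle_and_is_monotone(self, p):
        adj = bh_adjust(p)
        assert adj == pytest.approx(bh_step_up(p), abs=1e-12)
        assert all(a >= raw - 1e-12 for a, raw in zip(adj, p))
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


class TestRunComparisons:
    def test_single_test_plan_fdr_equals_raw(self, small_cohort):
        plan = ComparisonPlan("solo", [
            Comparison("extra_density", "stage", ("primary", "late_met"),
                       metric="count_density")])
        reports = run_comparisons(small_cohort["records"],
                                  small_cohort["metadata"], plan)
        assert len(reports) == 1
        assert reports[0].p_fdr == pytest.approx(reports[0].p_raw)

    def test_metastatic_extratumoral_density_higher(self, small_cohort):
        reports = run_comparisons(small_cohort["records"],
                                  small_cohort["metadata"], "primary_vs_metastatic")
        by_id = {r.comparison_id: r for r in reports}
        r = by_id["extratumoral_density"]
        assert r.effect["metastatic"] > r.effect["primary"]
        assert r.p_fdr < 0.05

    def test_missing_group_skipped_with_warning(self, small_cohort):
        plan = ComparisonPlan("ghost", [
            Comparison("nope", "stage", ("primary", "early_met"),
                       metric="count_density")])
        with pytest.warns(UserWarning, match="empty group"):
            reports = run_comparisons(small_cohort["records"],
                                      small_cohort["metadata"], plan)
        assert reports == []

    def test_band_comparison_runs(self, small_cohort):
        reports = run_comparisons(small_cohort["records"],
                                  small_cohort["metadata"], "extratumoral_bands")
        assert len(reports) == 1
        assert reports[0].test == "wilcoxon_rank_sum"

    def test_fdr_at_least_raw_within_family(self, small_cohort):
        reports = run_comparisons(small_cohort["records"],
                                  small_cohort["metadata"], "primary_vs_metastatic")
        assert all(r.p_fdr >= r.p_raw - 1e-12 for r in reports)
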