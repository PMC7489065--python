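"""Evaluation machinery: criteria, NRMSE, chi-square, ablation, influence."""

import datetime as dt

import numpy as np
import pytest
from scipy import stats

from vmango.architecture import TreeArchitecture
from vmango.evaluation import (
    ABLATION_FACTORS,
    CRITERIA,
    CriterionSeries,
    ablated_parameters,
    chi_square_compare,
    compute_criteria,
    influence_index,
    marginalize_table,
    mean_criteria,
    nrmse,
)
from vmango.parameters import DistributionSpec, ProbabilityTable


def series(name, bins, counts):
    return CriterionSeries(name, tuple(bins), counts)


class TestComputeCriteria:
    def test_empty_architecture_gives_zero_series(self):
        crit = compute_criteria([TreeArchitecture()], [1, 2])
        assert crit["gu_demography_monthly"].counts.sum() == 0
        assert crit["fruit_count_per_cycle"].counts.tolist() == [0.0, 0.0]

    def test_single_burst_counted_in_its_month(self):
        arch = TreeArchitecture()
        root = arch.add_ancestor("apical", "quiescent", dt.date(2003, 9, 1), cycle=0)
        arch.add_daughters(root, True, 0, dt.date(2003, 10, 12), cycle=1)
        crit = compute_criteria([arch], [1])
        assert crit["gu_demography_monthly"].as_dict() == {(2003, 10): 1.0}

    def test_axis_histogram_total_equals_gu_count(self, sim_archs):
        crit = compute_criteria(sim_archs, [1, 2])
        in_range = sum(
            1 for a in sim_archs for gu in a.gus.values() if gu.cycle in (1, 2)
        )
        hist = crit["axis_length_distribution"]
        assert sum(b * c for b, c in zip(hist.bins, hist.counts)) == in_range


class TestNrmse:
    def test_identical_series_give_zero(self):
        a = series("gu_demography_monthly", [1, 2, 3], [4, 5, 6])
        assert nrmse(a, a) == 0.0

    def test_hand_computed_example(self):
        ref = series("gu_demography_monthly", [1, 2], [0.0, 10.0])
        model = series("gu_demography_monthly", [1, 2], [1.0, 9.0])
        # RMSE = 1, range = 10
        assert nrmse(model, ref) == pytest.approx(0.1)

    def test_constant_reference_rejected(self):
        ref = series("gu_demography_monthly", [1, 2], [5.0, 5.0])
        model = series("gu_demography_monthly", [1, 2], [4.0, 6.0])
        with pytest.raises(ZeroDivisionError):
            nrmse(model, ref)

    def test_bin_alignment_fills_zeros(self):
        ref = series("gu_demography_monthly", [1, 2], [0.0, 10.0])
        model = series("gu_demography_monthly", [2, 3], [9.0, 1.0])
        # aligned bins (1,2,3): ref (0,10,0), model (0,9,1) -> rmse sqrt(2/3)
        assert nrmse(model, ref) == pytest.approx(np.sqrt(2 / 3) / 10)


class TestChiSquare:
    def test_identical_distributions(self):
        a = series("fruit_count_per_cycle", [1, 2], [10.0, 20.0])
        out = chi_square_compare(a, a)
        assert out["statistic"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_disjoint_support(self):
        a = series("fruit_count_per_cycle", [1, 2], [10.0, 0.0])
        b = series("fruit_count_per_cycle", [1, 2], [0.0, 10.0])
        out = chi_square_compare(a, b)
        assert out["p"] == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_three_bins(self):
        a = series("fruit_count_per_cycle", [1, 2, 3], [10.0, 20.0, 30.0])
        b = series("fruit_count_per_cycle", [1, 2, 3], [20.0, 20.0, 20.0])
        out = chi_square_compare(a, b)
        # expected (20,20,20); statistic = 100/20 + 0 + 100/20 = 10, dof 2
        assert out["statistic"] == pytest.approx(10.0)
        assert out["p"] == pytest.approx(stats.chi2.sf(10.0, 2))


class TestMarginalization:
    def test_bernoulli_frequency_weighted_collapse(self, params):
        table = params.table("has_lateral_daughters")
        collapsed = marginalize_table(
            table, "mother_position", {"apical": 3, "lateral": 1}
        )
        assert collapsed.factors == ()
        assert collapsed.rows[()].params["p"] == pytest.approx(0.75 * 0.66 + 0.25 * 0.28)

    def test_unweighted_collapse_is_uniform(self, params):
        collapsed = marginalize_table(params.table("has_lateral_daughters"), "mother_position")
        assert collapsed.rows[()].params["p"] == pytest.approx((0.66 + 0.28) / 2)

    def test_truncated_poisson_collapse_preserves_mean(self, params):
        from vmango.parameters import truncated_poisson_mean

        table = params.table("n_lateral_daughters_between")
        collapsed = marginalize_table(table, "ancestor_fate", {"quiescent": 1, "flowering": 1,
                                                               "fruiting": 2})
        got = truncated_poisson_mean(collapsed.rows[()].params["rate"])
        assert got == pytest.approx((2.4 + 3.4 + 2 * 4.2) / 4)

    def test_gaussian_moment_matching(self):
        table = ProbabilityTable(
            "gu_axis_length",
            ("position", "mother_position"),
            {
                ("apical", "apical"): DistributionSpec("gaussian", {"mean": 18.1, "sd": 4.1}),
                ("apical", "lateral"): DistributionSpec("gaussian", {"mean": 13.8, "sd": 4.0}),
            },
        )
        collapsed = marginalize_table(table, "mother_position")
        spec = collapsed.rows[("apical",)]
        assert spec.params["mean"] == pytest.approx((18.1 + 13.8) / 2)
        expected_var = 0.5 * (4.1**2 + 18.1**2) + 0.5 * (4.0**2 + 13.8**2) - 15.95**2
        assert spec.params["sd"] == pytest.approx(np.sqrt(expected_var))

    def test_factor_absent_is_noop(self, params):
        table = params.table("fruiting")
        assert marginalize_table(table, "mother_position") is table

    def test_ablating_all_factors_leaves_single_row_tables(self, params):
        null = ablated_parameters(params, list(ABLATION_FACTORS))
        for pid in ("vegetative_burst_within", "flowering", "has_lateral_daughters"):
            factors = null.tables[pid].factors
            assert not set(factors) & set(ABLATION_FACTORS)


class TestInfluenceIndex:
    def test_exactly_one_when_ablated_equals_null(self, params, weather, ancestor_sets):
        """Starting from an already factor-free model, ablating any single
        factor and ablating all factors yield the same model, so the index
        is exactly 1 for every criterion."""
        null_params = ablated_parameters(params, list(ABLATION_FACTORS))
        idx = influence_index(
            null_params, "mother_position", ancestor_sets[:2], weather,
            n_cycles=2, n_sims=8, seed=2,
        )
        for name in CRITERIA:
            assert idx[name] == pytest.approx(1.0)

    def test_small_when_ablated_equals_complete(self, params, weather, ancestor_sets):
        """No default table is keyed by ancestor position, so its ablation
        leaves the complete model unchanged and the index tends to zero."""
        idx = influence_index(
            params, "ancestor_position", ancestor_sets[:2], weather,
            n_cycles=2, n_sims=60, seed=2,
        )
        for name in CRITERIA:
            assert 0.0 <= idx[name] < 0.6

    def test_burst_date_is_the_dominant_factor(self, params, weather, ancestor_sets):
        """Removing the mother burst date degrades the GU demography more
        than removing the mother position."""
        kwargs = dict(n_cycles=2, n_sims=40, seed=4)
        idx_date = influence_index(
            params, "mother_burst_date", ancestor_sets[:2], weather, **kwargs
        )
        idx_pos = influence_index(
            params, "mother_position", ancestor_sets[:2], weather, **kwargs
        )
        assert idx_date["gu_demography_monthly"] > idx_pos["gu_demography_monthly"]


class TestAveragingConvergence:
    def test_more_simulations_reduce_mean_series_error(self, params, weather, ancestor_sets):
        """Two independent 60-run means of the same model are closer (in
        NRMSE) than two independent 6-run means."""
        from vmango.automata import simulate_trees

        def mean_of(n, seed0):
            sims = []
            for k in range(n):
                archs = simulate_trees(
                    ancestor_sets[:2], weather, params, 2, seed0 + k, grow_fruits=False
                )
                sims.append(compute_criteria(archs, [1, 2]))
            return mean_criteria(sims)

        big_a, big_b = mean_of(60, 1000), mean_of(60, 2000)
        small_a, small_b = mean_of(6, 3000), mean_of(6, 4000)
        name = "gu_demography_monthly"
        assert nrmse(big_a[name], big_b[name]) < nrmse(small_a[name], small_b[name])
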