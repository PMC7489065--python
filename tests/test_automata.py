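"""Stochastic automata: frequency recovery, chaining invariants, determinism."""

import datetime as dt

import numpy as np
import pytest
from scipy import stats

from vmango.automata import (
    FactorContext,
    bloom_window_of,
    flowering_step,
    fruiting_step,
    run_growing_cycles,
    sample_burst_day,
    simulate_trees,
    vegetative_burst_step,
)
from vmango.fixtures import AncestorSpec
from vmango.parameters import DistributionSpec

N = 10_000


def three_sigma(p, n=N):
    return 3 * np.sqrt(p * (1 - p) / n)


def ctx_within(month=9, position="apical", fate="quiescent", cycle=1):
    return FactorContext(
        mother_burst_date=month,
        mother_position=position,
        ancestor_position="apical",
        ancestor_fate=fate,
        cycle=cycle,
    )


class TestSampleBurstDay:
    def test_february_non_leap(self, rng):
        days = {sample_burst_day(("month", 2003, 2), rng).day for _ in range(500)}
        assert days <= set(range(1, 29))

    def test_week_window(self, rng):
        start = dt.date(2004, 9, 6)
        days = [sample_burst_day(("week", start), rng) for _ in range(500)]
        assert all(start <= d <= start + dt.timedelta(days=6) for d in days)

    def test_uniform_over_month_days(self, rng):
        """Chi-square goodness of fit against the uniform day distribution."""
        draws = [sample_burst_day(("month", 2003, 9), rng).day for _ in range(N)]
        counts = np.bincount(draws, minlength=31)[1:31]
        assert stats.chisquare(counts).pvalue > 1e-3


class TestVegetativeBurstStep:
    def test_burst_fraction_matches_table(self, params, rng):
        """August-December mothers burst within cycle at the printed 0.80."""
        hits = sum(
            vegetative_burst_step(ctx_within(month=rng.choice([8, 9, 10, 11, 12])), params, rng)
            is not None
            for _ in range(N)
        )
        assert abs(hits / N - 0.80) < three_sigma(0.80)

    def test_apical_fraction_matches_table(self, params, rng):
        """Conditional on bursting, an apical daughter occurs at 0.98."""
        decisions = []
        while len(decisions) < N:
            d = vegetative_burst_step(ctx_within(), params, rng)
            if d is not None:
                decisions.append(d)
        frac = sum(d.apical for d in decisions) / N
        assert abs(frac - 0.98) < three_sigma(0.98)

    def test_lateral_count_conditional_mean(self, params, rng):
        """Apical cycle-1 mothers average 2.1 laterals when laterals occur."""
        counts = []
        while len(counts) < N:
            d = vegetative_burst_step(ctx_within(), params, rng)
            if d is not None and d.n_lateral > 0:
                counts.append(d.n_lateral)
        counts = np.array(counts)
        assert abs(counts.mean() - 2.1) < 3 * counts.std() / np.sqrt(N)

    def test_zero_probability_context_never_bursts(self, params, rng):
        p = params.copy()
        p.tables["vegetative_burst_within"].rows[(9,)] = DistributionSpec(
            "bernoulli", {"p": 0.0}
        )
        assert all(
            vegetative_burst_step(ctx_within(month=9), p, rng) is None for _ in range(300)
        )

    def test_degenerate_bernoullis_give_single_apical(self, params, rng):
        p = params.copy()
        p.tables["vegetative_burst_within"].rows[(9,)] = DistributionSpec("bernoulli", {"p": 1.0})
        p.tables["has_apical_daughter"].rows[()] = DistributionSpec("bernoulli", {"p": 1.0})
        p.tables["has_lateral_daughters"].rows[("apical",)] = DistributionSpec(
            "bernoulli", {"p": 0.0}
        )
        for _ in range(50):
            d = vegetative_burst_step(ctx_within(month=9), p, rng)
            assert d is not None and d.apical and d.n_lateral == 0

    def test_no_apical_guarantees_laterals(self, params, rng):
        p = params.copy()
        p.tables["vegetative_burst_within"].rows[(9,)] = DistributionSpec("bernoulli", {"p": 1.0})
        p.tables["has_apical_daughter"].rows[()] = DistributionSpec("bernoulli", {"p": 0.0})
        for _ in range(50):
            d = vegetative_burst_step(ctx_within(month=9), p, rng)
            assert d is not None and not d.apical and d.n_lateral >= 1

    def test_last_window_month_cannot_burst_within_cycle(self, params, rng):
        assert all(
            vegetative_burst_step(ctx_within(month=5), params, rng) is None for _ in range(300)
        )

    def test_between_cycle_apical_consumed_by_flowering(self, params, rng):
        for fate in ("flowering", "fruiting"):
            ctx = FactorContext(9, "apical", "apical", fate, cycle=2, between=True)
            for _ in range(200):
                d = vegetative_burst_step(ctx, params, rng)
                if d is not None:
                    assert not d.apical


class TestFloweringStep:
    def test_mixed_fraction(self, params, rng):
        """Mixed inflorescences occur at the printed 0.06."""
        mixed = sum(
            (d := flowering_step(ctx_within(), params, rng)) is not None and d.kind == "mixed"
            for _ in range(N)
        )
        assert abs(mixed / N - 0.06) < three_sigma(0.06)

    def test_mixed_is_single_inflorescence(self, params, rng):
        seen = 0
        while seen < 50:
            d = flowering_step(ctx_within(), params, rng)
            if d is not None and d.kind == "mixed":
                assert d.n_inflorescences == 1
                seen += 1

    def test_zero_probability_context_never_flowers(self, params, rng):
        p = params.copy()
        p.tables["is_mixed_inflorescence"].rows[()] = DistributionSpec("bernoulli", {"p": 0.0})
        for key in list(p.tables["flowering"].rows):
            p.tables["flowering"].rows[key] = DistributionSpec("bernoulli", {"p": 0.0})
        assert all(flowering_step(ctx_within(), p, rng) is None for _ in range(300))


class TestFruitingStep:
    def test_late_bloom_never_fruits(self, params, rng):
        late = dt.date(2004, 10, 20)
        assert bloom_window_of(late) == "late"
        assert all(
            fruiting_step(ctx_within(), late, 1, params, rng) is None for _ in range(300)
        )

    def test_early_bloom_fraction(self, params, rng):
        """Early-bloom GUs set fruit at the printed 0.40."""
        early = dt.date(2004, 9, 1)
        hits = sum(
            fruiting_step(ctx_within(), early, 1, params, rng) is not None for _ in range(N)
        )
        assert abs(hits / N - 0.40) < three_sigma(0.40)

    def test_fruit_counts_positive(self, params, rng):
        early = dt.date(2004, 9, 1)
        counts = [fruiting_step(ctx_within(), early, 3, params, rng) for _ in range(300)]
        assert all(c is None or c >= 1 for c in counts)


class TestRunGrowingCycles:
    def test_zero_probability_tables_leave_architecture_unchanged(self, params, weather):
        p = params.copy()
        for pid in ("vegetative_burst_within", "vegetative_burst_between",
                    "is_mixed_inflorescence", "mixed_burst"):
            for key in list(p.tables[pid].rows):
                p.tables[pid].rows[key] = DistributionSpec("bernoulli", {"p": 0.0})
        for key in list(p.tables["flowering"].rows):
            p.tables["flowering"].rows[key] = DistributionSpec("bernoulli", {"p": 0.0})
        ancestors = [AncestorSpec("apical", "quiescent", dt.date(2002, 10, 5))]
        arch = run_growing_cycles(ancestors, weather, p, 2, np.random.default_rng(0))
        assert len(arch.gus) == 1
        assert len(arch.inflorescences) == 0 and len(arch.fruits) == 0

    def test_fixed_seed_reproduces_event_log(self, params, weather, ancestor_sets):
        a = simulate_trees(ancestor_sets, weather, params, 2, seed=11)
        b = simulate_trees(ancestor_sets, weather, params, 2, seed=11)
        for x, y in zip(a, b):
            assert x.events == y.events
            assert x.decisions == y.decisions

    def test_different_seeds_differ(self, params, weather, ancestor_sets):
        a = simulate_trees(ancestor_sets, weather, params, 2, seed=11)
        b = simulate_trees(ancestor_sets, weather, params, 2, seed=12)
        assert any(x.events != y.events for x, y in zip(a, b))

    def test_adding_trees_preserves_earlier_streams(self, params, weather, ancestor_sets):
        a = simulate_trees(ancestor_sets[:2], weather, params, 2, seed=11)
        b = simulate_trees(ancestor_sets, weather, params, 2, seed=11)
        for x, y in zip(a, b[:2]):
            assert x.events == y.events

    def test_fate_partition(self, sim_archs):
        """Every season-end terminal has a definite fate; fruiting implies
        flowering (an inflorescence exists)."""
        for arch in sim_archs:
            for gid in arch.terminal_gus():
                gu = arch.gus[gid]
                assert gu.fate in {"quiescent", "flowering", "fruiting"}
            for fr in arch.fruits.values():
                bearer = arch.gus[fr.bearer_id]
                assert bearer.fate_history[fr.cycle] == "fruiting"
                assert arch.inflos_of[fr.bearer_id]

    def test_path_exclusivity(self, sim_archs):
        """A GU that burst within a cycle is never a flowering candidate of
        the same cycle."""
        for arch in sim_archs:
            bursters = {
                (d["gu_id"], d["cycle"])
                for d in arch.decisions
                if d["process"] == "vegetative_burst_within" and d["response"] == 1
            }
            flower_tests = {
                (d["gu_id"], d["cycle"])
                for d in arch.decisions
                if d["process"] in ("flowering", "is_mixed_inflorescence")
            }
            assert not (bursters & flower_tests)

    def test_apical_bud_consumption_in_logs(self, sim_archs):
        """No between-cycle apical daughter for flowering/fruiting ancestors."""
        for arch in sim_archs:
            for d in arch.decisions:
                if (
                    d["process"] == "has_apical_daughter_between"
                    and d["ancestor_fate"] in ("flowering", "fruiting")
                ):
                    assert d["response"] == 0

    def test_flush_peaks_separated_by_months(self, params, weather, ancestor_sets):
        """GU production shows distinct flushes a few months apart."""
        archs = simulate_trees(ancestor_sets, weather, params, 2, seed=5, grow_fruits=False)
        months = {}
        for arch in archs:
            for gu in arch.gus.values():
                if gu.cycle >= 1:
                    key = (gu.burst_date.year, gu.burst_date.month)
                    months[key] = months.get(key, 0) + 1
        assert len(months) >= 6  # production spread over several flush months
        # at least two local flush maxima separated by two or more months
        keys = sorted(months)
        series = [months[k] for k in keys]
        peaks = [
            i
            for i in range(len(series))
            if (i == 0 or series[i] >= series[i - 1])
            and (i == len(series) - 1 or series[i] > series[i + 1])
        ]
        assert len(peaks) >= 2
        i, j = peaks[0], peaks[-1]
        gap = (keys[j][0] - keys[i][0]) * 12 + keys[j][1] - keys[i][1]
        assert gap >= 2
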