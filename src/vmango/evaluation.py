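"""Model evaluation: global criteria, NRMSE, chi-square, influence index.

Simulated architectures are summarized by four global structural and
temporal criteria:

- C1 ``gu_demography_monthly``: number of GUs bursting each month;
- C2 ``inflo_demography_weekly``: number of inflorescences at full bloom
  each week;
- C3 ``fruit_count_per_cycle``: total fruits produced per growing cycle;
- C4 ``axis_length_distribution``: histogram of axis lengths (in GUs) at
  the end of the simulated period.

A model's mean series (criterion averaged over many simulations) is
compared with a reference through the root mean square error normalized by
the reference range (NRMSE), and through a classical chi-square test on the
binned counts.

The influence of a conditioning factor F_j is quantified by ablation: a
model M_j is built by marginalizing F_j out of every probability table
(rows collapsed by frequency-weighted averaging, the frequencies being the
factor-level occupancies observed in the complete model's own simulations),
and a null model M_0 by marginalizing all four factors.  The influence
index is

    I(C_i, F_j) = NRMSE_i(M_j, M_c) / NRMSE_i(M_0, M_c),

with the complete model's mean series as the reference: values near 0 mark
a negligible factor, values >= 1 a factor whose omission disrupts the
simulation more than ignoring all factors.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .architecture import TreeArchitecture
from .automata import simulate_trees
from .parameters import (
    DistributionSpec,
    ParameterSet,
    ProbabilityTable,
    ValidationError,
    truncated_poisson_rate_for_mean,
)

__all__ = [
    "CriterionSeries",
    "CRITERIA",
    "ABLATION_FACTORS",
    "compute_criteria",
    "mean_criteria",
    "nrmse",
    "chi_square_compare",
    "marginalize_table",
    "ablated_parameters",
    "influence_index",
]

CRITERIA = (
    "gu_demography_monthly",
    "inflo_demography_weekly",
    "fruit_count_per_cycle",
    "axis_length_distribution",
)

ABLATION_FACTORS = (
    "mother_burst_date",
    "mother_position",
    "ancestor_position",
    "ancestor_fate",
)


@dataclass
class CriterionSeries:
    criterion: str
    bins: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bins = tuple(self.bins)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bins) != len(self.counts):
            raise ValidationError("bins and counts differ in length")
        if (self.counts < 0).any():
            raise ValidationError("criterion counts must be >= 0")

    def as_dict(self) -> dict:
        return dict(zip(self.bins, self.counts))


def _align(a: CriterionSeries, b: CriterionSeries) -> tuple[np.ndarray, np.ndarray]:
    """Union-of-bins alignment (missing bins count 0)."""
    if a.criterion != b.criterion:
        raise ValidationError(f"cannot align {a.criterion} with {b.criterion}")
    bins = sorted(set(a.bins) | set(b.bins), key=str)
    da, db = a.as_dict(), b.as_dict()
    return (
        np.array([da.get(k, 0.0) for k in bins]),
        np.array([db.get(k, 0.0) for k in bins]),
    )


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

def compute_criteria(
    archs: Sequence[TreeArchitecture],
    cycles: Iterable[int],
) -> dict[str, CriterionSeries]:
    """The four global criteria of a set of simulated trees."""
    cycles = sorted(set(cycles))
    cycset = set(cycles)

    monthly: dict[tuple[int, int], float] = {}
    weekly: dict[tuple[int, int], float] = {}
    per_cycle: dict[int, float] = {c: 0.0 for c in cycles}
    axis_counts: dict[int, float] = {}

    for arch in archs:
        for gu in arch.gus.values():
            if gu.cycle in cycset:
                key = (gu.burst_date.year, gu.burst_date.month)
                monthly[key] = monthly.get(key, 0.0) + 1
        for inf in arch.inflorescences.values():
            if inf.cycle in cycset:
                iso = inf.full_bloom_date.isocalendar()
                key = (iso[0], iso[1])
                weekly[key] = weekly.get(key, 0.0) + 1
        for fr in arch.fruits.values():
            if fr.cycle in cycset:
                per_cycle[fr.cycle] = per_cycle.get(fr.cycle, 0.0) + 1
        for length in arch.extract_axes(cycles):
            axis_counts[length] = axis_counts.get(length, 0.0) + 1

    def series(name: str, mapping: Mapping) -> CriterionSeries:
        bins = tuple(sorted(mapping))
        return CriterionSeries(name, bins, [mapping[k] for k in bins])

    return {
        "gu_demography_monthly": series("gu_demography_monthly", monthly),
        "inflo_demography_weekly": series("inflo_demography_weekly", weekly),
        "fruit_count_per_cycle": series("fruit_count_per_cycle", per_cycle),
        "axis_length_distribution": series("axis_length_distribution", axis_counts),
    }


def mean_criteria(per_sim: Sequence[Mapping[str, CriterionSeries]]) -> dict[str, CriterionSeries]:
    """Average criterion series over simulations ('average simulation')."""
    out = {}
    for name in CRITERIA:
        bins = sorted({b for sim in per_sim for b in sim[name].bins}, key=str)
        acc = np.zeros(len(bins))
        for sim in per_sim:
            d = sim[name].as_dict()
            acc += np.array([d.get(k, 0.0) for k in bins])
        out[name] = CriterionSeries(name, tuple(bins), acc / max(len(per_sim), 1))
    return out


# ---------------------------------------------------------------------------
# Error measures
# ---------------------------------------------------------------------------

def nrmse(model_mean: CriterionSeries, reference: CriterionSeries) -> float:
    """Root mean square error of the model mean series against the
    reference, normalized by the reference range (max - min)."""
    ref, mod = _align(reference, model_mean)
    rng = ref.max() - ref.min()
    if rng <= 0:
        raise ZeroDivisionError(
            f"reference series for {reference.criterion} is constant; NRMSE undefined"
        )
    rmse = float(np.sqrt(np.mean((ref - mod) ** 2)))
    return rmse / rng


def chi_square_compare(series_a: CriterionSeries, series_b: CriterionSeries) -> dict[str, float]:
    """Classical chi-square comparison of two binned count series.

    Expected counts come from ``series_b`` rescaled to the total of
    ``series_a``; bins where both series are zero are dropped.
    """
    a, b = _align(series_a, series_b)
    keep = (a > 0) | (b > 0)
    a, b = a[keep], b[keep]
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValidationError("chi-square comparison requires positive totals")
    expected = b * (a.sum() / b.sum())
    if ((expected == 0) & (a > 0)).any():
        return {"statistic": float("inf"), "p": 0.0}
    statistic = float(((a - expected) ** 2 / np.where(expected > 0, expected, 1.0)).sum())
    dof = max(len(a) - 1, 1)
    return {"statistic": statistic, "p": float(sstats.chi2.sf(statistic, dof))}


# ---------------------------------------------------------------------------
# Factor ablation
# ---------------------------------------------------------------------------

def _collapse_specs(specs: Sequence[DistributionSpec], weights: Sequence[float]) -> DistributionSpec:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    family = specs[0].family
    if any(s.family != family for s in specs):
        raise ValidationError("cannot collapse rows of different families")
    if family == "bernoulli":
        return DistributionSpec("bernoulli", {"p": float(np.dot(w, [s.params["p"] for s in specs]))})
    if family == "poisson-truncated":
        mean = float(np.dot(w, [s.mean() for s in specs]))
        return DistributionSpec("poisson-truncated", {"rate": truncated_poisson_rate_for_mean(mean)})
    if family == "ordinal-multinomial":
        cats = sorted({c for s in specs for c in s.params["categories"]}, key=str)
        probs = np.zeros(len(cats))
        index = {c: i for i, c in enumerate(cats)}
        for wi, s in zip(w, specs):
            for c, p in zip(s.params["categories"], s.params["probs"]):
                probs[index[c]] += wi * p
        return DistributionSpec(
            "ordinal-multinomial", {"categories": cats, "probs": (probs / probs.sum()).tolist()}
        )
    if family == "gaussian":
        means = np.array([s.params["mean"] for s in specs])
        sds = np.array([s.params["sd"] for s in specs])
        m = float(np.dot(w, means))
        v = float(np.dot(w, sds**2 + means**2) - m**2)
        return DistributionSpec("gaussian", {"mean": m, "sd": max(np.sqrt(max(v, 0.0)), 1e-6)})
    if family == "gamma":
        means = np.array([s.params["shape"] * s.params["scale"] for s in specs])
        variances = np.array([s.params["shape"] * s.params["scale"] ** 2 for s in specs])
        m = float(np.dot(w, means))
        v = float(np.dot(w, variances + means**2) - m**2)
        v = max(v, 1e-9)
        return DistributionSpec("gamma", {"shape": m**2 / v, "scale": v / m})
    raise ValidationError(f"no marginalization rule for family {family}")


def marginalize_table(
    table: ProbabilityTable,
    factor: str,
    level_weights: Optional[Mapping] = None,
) -> ProbabilityTable:
    """Collapse one factor out of a probability table.

    Rows sharing the remaining factor levels are averaged, weighted by the
    observed frequency of the collapsed factor's levels (uniform when no
    frequencies are supplied or a level is unobserved).
    """
    if factor not in table.factors:
        return table
    idx = table.factors.index(factor)
    remaining = tuple(f for i, f in enumerate(table.factors) if i != idx)
    grouped: dict[tuple, list[tuple[DistributionSpec, float]]] = {}
    for key, spec in table.rows.items():
        level = key[idx]
        w = 1.0
        if level_weights:
            w = float(level_weights.get(level, 0.0))
        rkey = tuple(v for i, v in enumerate(key) if i != idx)
        grouped.setdefault(rkey, []).append((spec, w))
    rows = {}
    for rkey, pairs in grouped.items():
        specs = [p[0] for p in pairs]
        weights = [p[1] for p in pairs]
        if sum(weights) <= 0:
            weights = [1.0] * len(specs)
        rows[rkey] = _collapse_specs(specs, weights)
    return ProbabilityTable(table.process_id, remaining, rows)


def _level_frequencies(archs: Sequence[TreeArchitecture], factor: str) -> dict:
    counts: dict = {}
    for arch in archs:
        for decision in arch.decisions:
            level = decision.get(factor)
            if level is not None:
                counts[level] = counts.get(level, 0) + 1
    return counts


def ablated_parameters(
    params: ParameterSet,
    factors: Sequence[str],
    reference_archs: Sequence[TreeArchitecture] = (),
) -> ParameterSet:
    """Parameter set with the given factors marginalized out of every table."""
    out = params.copy()
    for factor in factors:
        if factor not in ABLATION_FACTORS:
            raise ValidationError(f"{factor!r} is not an ablation factor")
        weights = _level_frequencies(reference_archs, factor) if reference_archs else None
        for pid, table in list(out.tables.items()):
            out.tables[pid] = marginalize_table(table, factor, weights)
    return out


# ---------------------------------------------------------------------------
# Influence index
# ---------------------------------------------------------------------------

def _simulate_mean(params, ancestor_sets, weather, n_cycles, seeds, grow_fruits=True):
    sims = []
    archsets = []
    for s in seeds:
        archs = simulate_trees(ancestor_sets, weather, params, n_cycles, int(s),
                               grow_fruits=grow_fruits)
        archsets.append(archs)
        sims.append(compute_criteria(archs, range(1, n_cycles + 1)))
    return mean_criteria(sims), archsets


def influence_index(
    params: ParameterSet,
    factor: str,
    ancestor_sets,
    weather,
    n_cycles: int = 2,
    n_sims: int = 1000,
    seed: int = 1,
    criteria: Sequence[str] = CRITERIA,
) -> dict[str, float]:
    """Influence index I(C_i, F_j) of one factor on each global criterion.

    The complete model's mean series over ``n_sims`` independent runs is
    the reference; the ablated model M_j and the null model M_0 are run on
    a common, independent stream of ``n_sims`` seeds (so that when M_j and
    M_0 coincide the index is exactly 1).
    """
    seed_rng = np.random.default_rng(seed)
    ref_seeds = seed_rng.integers(0, 2**30, size=n_sims)
    cand_seeds = seed_rng.integers(0, 2**30, size=n_sims)

    # none of the four criteria depends on fruit mass trajectories, so the
    # expansion phase is skipped in these runs
    ref_mean, ref_archsets = _simulate_mean(
        params, ancestor_sets, weather, n_cycles, ref_seeds, grow_fruits=False
    )
    ref_archs = [a for archs in ref_archsets for a in archs]

    params_j = ablated_parameters(params, [factor], ref_archs)
    params_0 = ablated_parameters(params, list(ABLATION_FACTORS), ref_archs)

    mean_j, _ = _simulate_mean(params_j, ancestor_sets, weather, n_cycles, cand_seeds,
                               grow_fruits=False)
    mean_0, _ = _simulate_mean(params_0, ancestor_sets, weather, n_cycles, cand_seeds,
                               grow_fruits=False)

    out = {}
    for name in criteria:
        denom = nrmse(mean_0[name], ref_mean[name])
        if denom == 0:
            raise ZeroDivisionError(
                f"null-model NRMSE is zero for {name}; influence index degenerate"
            )
        out[name] = nrmse(mean_j[name], ref_mean[name]) / denom
    return out
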