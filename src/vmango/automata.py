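"""Stochastic developmental automata and the growing-cycle simulator.

Each terminal growth unit (GU) passes through a chain of elementary
stochastic processes — occurrence (binomial), intensity (zero-truncated
Poisson) and timing (ordinal multinomial) — forming three automata:

- vegetative burst: does the GU produce daughters? is one apical? are there
  laterals, and how many? in which month do they appear (then a uniformly
  chosen day of that month)?
- flowering: are mixed inflorescences produced (then exactly one, apical)?
  otherwise does flowering occur, with how many pure inflorescences and
  which bloom week (then a uniform day of that week)?
- fruiting: does a flowering GU set fruit (probability keyed by its bloom
  window), and how many fruits?

The automata are conditioned by structural and temporal factors: the
mother GU's burst date (month) and position, and the previous-cycle
ancestor GU's position and fate.  Between-cycle vegetative burst is a
separate automaton keyed by ancestor fate: only quiescent ancestors can
produce an apical daughter (the apical bud of flowering and fruiting
ancestors was consumed by the inflorescence).

:func:`run_growing_cycles` chains these automata over successive
overlapping growing cycles: between-cycle burst on the ancestors, the
within-cycle automaton on every new terminal (daughters of post-December
GUs being deferred to the next cycle through the low late-season
probabilities and the between-cycle tables), mixed-inflorescence daughter
production in December-February, then flowering and fruiting on the
season-end terminals, whose fates seed the next cycle.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .architecture import TreeArchitecture
from .fixtures import AncestorSpec, WeatherSeries
from .fruit_growth import FruitingBranchContext, get_expansion_model, simulate_branch_fruit_growth
from .organ_growth import gu_geometry, inflorescence_geometry, pipe_update_diameter
from .parameters import ParameterError, ParameterSet

__all__ = [
    "FactorContext",
    "BurstDecision",
    "FloweringDecision",
    "vegetative_burst_step",
    "flowering_step",
    "fruiting_step",
    "sample_burst_day",
    "bloom_window_of",
    "run_growing_cycles",
    "simulate_trees",
]


@dataclass(frozen=True)
class FactorContext:
    """Factor levels conditioning one automaton decision."""

    mother_burst_date: int            # calendar month 1..12
    mother_position: str
    ancestor_position: str
    ancestor_fate: str
    cycle: int
    between: bool = False


@dataclass(frozen=True)
class BurstDecision:
    apical: bool
    n_lateral: int
    burst_month: int
    burst_day: dt.date


@dataclass(frozen=True)
class FloweringDecision:
    kind: str                 # "mixed" | "pure"
    n_inflorescences: int
    bloom_week: int
    bloom_day: dt.date


# ---------------------------------------------------------------------------
# Calendar helpers
# ---------------------------------------------------------------------------

def _month_year(month: int, cycle: int, start_year: int) -> int:
    """Calendar year of a vegetative-window month within a given cycle.

    Cycle c's vegetative season runs August (start_year + c - 1) through May
    (start_year + c); its flowering and harvest periods fall later the same
    cycle and are handled separately.
    """
    return start_year + cycle - 1 if month >= 8 else start_year + cycle


def sample_burst_day(period: tuple, rng: np.random.Generator) -> dt.date:
    """Uniformly sample a calendar day within a month or week period.

    ``period`` is ``("month", year, month)`` or ``("week", start_date)``
    (a 7-day window).
    """
    if period[0] == "month":
        _, year, month = period
        n_days = calendar.monthrange(year, month)[1]
        return dt.date(year, month, int(rng.integers(1, n_days + 1)))
    if period[0] == "week":
        _, start = period
        return start + dt.timedelta(days=int(rng.integers(0, 7)))
    raise ParameterError(f"unknown period kind {period[0]!r}")


def bloom_window_of(bloom_date: dt.date) -> str:
    """Fruit-set window of a bloom date: early (to 15 Sep), mid (to 15 Oct),
    late (after)."""
    y = bloom_date.year
    if bloom_date <= dt.date(y, 9, 15):
        return "early"
    if bloom_date <= dt.date(y, 10, 15):
        return "mid"
    return "late"


def _months_after(month: int, window: Sequence[int]) -> list[int]:
    order = list(window)
    if month not in order:
        return []
    return order[order.index(month) + 1:]


# ---------------------------------------------------------------------------
# Elementary automaton steps
# ---------------------------------------------------------------------------

def _record(arch: Optional[TreeArchitecture], process: str, gu_id: Optional[int],
            ctx: FactorContext, response) -> None:
    if arch is None:
        return
    arch.decisions.append(
        {
            "process": process,
            "gu_id": gu_id,
            "cycle": ctx.cycle,
            "mother_burst_date": ctx.mother_burst_date,
            "mother_position": ctx.mother_position,
            "ancestor_position": ctx.ancestor_position,
            "ancestor_fate": ctx.ancestor_fate,
            "response": response,
        }
    )


def vegetative_burst_step(
    ctx: FactorContext,
    params: ParameterSet,
    rng: np.random.Generator,
    arch: Optional[TreeArchitecture] = None,
    gu_id: Optional[int] = None,
) -> Optional[BurstDecision]:
    """One pass of the vegetative automaton for a terminal GU.

    Returns ``None`` when no burst occurs.  Within-cycle decisions are keyed
    by the mother's burst month and position; between-cycle decisions by the
    ancestor's fate.  When the apical test is negative, all daughters are
    lateral and at least one lateral is guaranteed.
    """
    window = params.config.vegetative_months
    if ctx.between:
        pid = {
            "burst": "vegetative_burst_between",
            "apical": "has_apical_daughter_between",
            "lateral": "has_lateral_daughters_between",
            "n": "n_lateral_daughters_between",
            "month": "burst_month_between",
        }
        burst_p = params.table("vegetative_burst_between").lookup(ancestor_fate=ctx.ancestor_fate)
    else:
        pid = {
            "burst": "vegetative_burst_within",
            "apical": "has_apical_daughter",
            "lateral": "has_lateral_daughters",
            "n": "n_lateral_daughters",
            "month": "burst_month",
        }
        burst_p = params.table("vegetative_burst_within").lookup(
            mother_burst_date=ctx.mother_burst_date
        )
    burst = burst_p.sample(rng)
    _record(arch, pid["burst"], gu_id, ctx, int(burst))
    if not burst:
        return None

    # burst month: within-cycle months strictly later than the mother's;
    # between-cycle months come straight from the fate-keyed table.
    if ctx.between:
        month_spec = params.table("burst_month_between").lookup(ancestor_fate=ctx.ancestor_fate)
        month = int(month_spec.sample(rng))
    else:
        available = _months_after(ctx.mother_burst_date, window)
        if not available:
            # a mother bursting in the last window month cannot produce
            # daughters later the same cycle
            return None
        month_spec = params.table("burst_month").lookup(mother_burst_date=ctx.mother_burst_date)
        cats = list(month_spec.params["categories"])
        probs = np.asarray(month_spec.params["probs"], dtype=float)
        mask = np.array([c in available for c in cats])
        if not mask.any():
            return None
        probs = probs * mask
        probs = probs / probs.sum()
        month = int(np.asarray(cats)[np.searchsorted(np.cumsum(probs), rng.random())])

    if ctx.between:
        apical_spec = params.table("has_apical_daughter_between").lookup(
            ancestor_fate=ctx.ancestor_fate
        )
    else:
        apical_spec = params.table("has_apical_daughter").lookup()
    apical = apical_spec.sample(rng)
    _record(arch, pid["apical"], gu_id, ctx, int(apical))

    if apical:
        if ctx.between:
            lat_spec = params.table("has_lateral_daughters_between").lookup(
                ancestor_fate=ctx.ancestor_fate
            )
        else:
            lat_spec = params.table("has_lateral_daughters").lookup(
                mother_position=ctx.mother_position
            )
        has_lateral = lat_spec.sample(rng)
        _record(arch, pid["lateral"], gu_id, ctx, int(has_lateral))
    else:
        has_lateral = True  # all daughters lateral, at least one

    n_lateral = 0
    if has_lateral:
        if ctx.between:
            n_spec = params.table("n_lateral_daughters_between").lookup(
                ancestor_fate=ctx.ancestor_fate
            )
        else:
            n_spec = params.table("n_lateral_daughters").lookup(
                mother_position=ctx.mother_position, cycle=min(ctx.cycle, 2)
            )
        n_lateral = int(n_spec.sample(rng))
        _record(arch, pid["n"], gu_id, ctx, n_lateral)

    year = _month_year(month, ctx.cycle, params.config.start_year)
    day = sample_burst_day(("month", year, month), rng)
    _record(arch, pid["month"], gu_id, ctx, month)
    return BurstDecision(apical=bool(apical), n_lateral=n_lateral, burst_month=month, burst_day=day)


def flowering_step(
    ctx: FactorContext,
    params: ParameterSet,
    rng: np.random.Generator,
    arch: Optional[TreeArchitecture] = None,
    gu_id: Optional[int] = None,
) -> Optional[FloweringDecision]:
    """Flowering automaton for a season-end terminal GU.

    Mixed inflorescences are tested first; a positive draw yields exactly
    one mixed, apical inflorescence.  Otherwise a Bernoulli keyed by
    position and ancestor fate decides pure flowering, with a
    zero-truncated-Poisson inflorescence count and a multinomial bloom week.
    Only one type of inflorescence appears on a given GU.
    """
    flowering_year = params.config.start_year + ctx.cycle
    mixed = params.table("is_mixed_inflorescence").lookup().sample(rng)
    _record(arch, "is_mixed_inflorescence", gu_id, ctx, int(mixed))
    week_spec = params.table("bloom_week").lookup()
    if mixed:
        week = int(week_spec.sample(rng))
        start = dt.date(flowering_year, 7, 1) + dt.timedelta(weeks=week)
        day = sample_burst_day(("week", start), rng)
        return FloweringDecision(kind="mixed", n_inflorescences=1, bloom_week=week, bloom_day=day)

    flowering = params.table("flowering").lookup(
        mother_position=ctx.mother_position, ancestor_fate=ctx.ancestor_fate
    ).sample(rng)
    _record(arch, "flowering", gu_id, ctx, int(flowering))
    if not flowering:
        return None
    n = int(
        params.table("n_inflorescences")
        .lookup(mother_burst_date=ctx.mother_burst_date)
        .sample(rng)
    )
    _record(arch, "n_inflorescences", gu_id, ctx, n)
    week = int(week_spec.sample(rng))
    _record(arch, "bloom_week", gu_id, ctx, week)
    start = dt.date(flowering_year, 7, 1) + dt.timedelta(weeks=week)
    day = sample_burst_day(("week", start), rng)
    return FloweringDecision(kind="pure", n_inflorescences=n, bloom_week=week, bloom_day=day)


def fruiting_step(
    ctx: FactorContext,
    bloom_date: dt.date,
    n_inflorescences: int,
    params: ParameterSet,
    rng: np.random.Generator,
    arch: Optional[TreeArchitecture] = None,
    gu_id: Optional[int] = None,
) -> Optional[int]:
    """Fruit-set test and fruit count for a GU that flowered purely.

    The fruit-set probability is keyed by the bloom window (early / mid /
    late); the count is zero-truncated Poisson, increasing with the number
    of inflorescences.  Returns ``None`` when no fruit sets.
    """
    window = bloom_window_of(bloom_date)
    fruit_set = params.table("fruiting").lookup(bloom_window=window).sample(rng)
    _record(arch, "fruiting", gu_id, ctx, int(fruit_set))
    if not fruit_set:
        return None
    cls = "1" if n_inflorescences <= 1 else "2+"
    n = int(params.table("n_fruits").lookup(n_inflorescences_class=cls).sample(rng))
    _record(arch, "n_fruits", gu_id, ctx, n)
    return n


# ---------------------------------------------------------------------------
# Growing-cycle simulator
# ---------------------------------------------------------------------------

def _assign_gu_geometry(arch: TreeArchitecture, gid: int, mother_position: str,
                        params: ParameterSet, rng: np.random.Generator) -> None:
    gu = arch.gus[gid]
    geo = gu_geometry(gu.position, mother_position, params, rng)
    gu.geometry = geo
    gu.axis_length = geo["axis_length"]
    gu.n_leaves = geo["n_leaves"]
    gu.leaf_length = geo["common_leaf_length"]
    gu.diameter = geo["basal_diameter"]


def _update_pipe_diameters(arch: TreeArchitecture, descendant_counts: dict[int, int],
                           new_gid: int, params: ParameterSet) -> None:
    gu = arch.gus[new_gid]
    parent = gu.parent_id
    while parent is not None:
        descendant_counts[parent] = descendant_counts.get(parent, 0) + 1
        d = pipe_update_diameter(descendant_counts[parent], params.allometry)
        pgu = arch.gus[parent]
        if pgu.diameter is None or d > pgu.diameter:
            pgu.diameter = d
        parent = pgu.parent_id


def _inflo_burst_from_bloom(bloom: dt.date, weather: Optional[WeatherSeries],
                            params: ParameterSet) -> dt.date:
    """Back-compute the inflorescence burst date from full bloom.

    Walks backward from bloom accumulating stage E then stage D thermal
    sums (full bloom marks the onset of stage F).  Falls back to a 60-day
    offset when the weather series does not reach far enough back.
    """
    stages = [s for s in reversed(params.thermal.inflo_stages) if s.name in ("D", "E")]
    day = bloom
    for stage in stages:
        total = 0.0
        while total < stage.tts_threshold:
            day -= dt.timedelta(days=1)
            if weather is None or not weather.covers(day):
                return bloom - dt.timedelta(days=60)
            total += max(0.0, weather.temperature(day) - stage.base_T)
    return day


def run_growing_cycles(
    ancestors: Sequence[AncestorSpec],
    weather: Optional[WeatherSeries],
    params: ParameterSet,
    n_cycles: int,
    rng: np.random.Generator,
    grow_fruits: bool = True,
) -> TreeArchitecture:
    """Simulate one tree over ``n_cycles`` successive growing cycles.

    Fruit expansion requires a weather series covering the harvest periods;
    with ``grow_fruits=False`` (or insufficient weather) fruits are created
    with bloom anchors but no mass trajectory.
    """
    from .applications import identify_fruiting_branches

    arch = TreeArchitecture()
    descendant_counts: dict[int, int] = {}
    season_terminals: list[int] = []
    pending_mixed: list[tuple[int, int, bool, int]] = []  # (bearer, n, apical, month)

    for spec in ancestors:
        gid = arch.add_ancestor(spec.position, spec.fate, spec.burst_date, cycle=0)
        _assign_gu_geometry(arch, gid, "apical", params, rng)
        season_terminals.append(gid)

    for cycle in range(1, n_cycles + 1):
        veg_end = dt.date(params.config.start_year + cycle, 5, 31)
        queue: list[int] = []

        # ---- between-cycle vegetative burst on the ancestors -------------
        for anc_id in sorted(season_terminals):
            anc = arch.gus[anc_id]
            ctx = FactorContext(
                mother_burst_date=anc.burst_date.month,
                mother_position=anc.position,
                ancestor_position=anc.position,
                ancestor_fate=anc.fate,
                cycle=cycle,
                between=True,
            )
            decision = vegetative_burst_step(ctx, params, rng, arch, anc_id)
            if decision is None:
                continue
            new_ids = arch.add_daughters(
                anc_id,
                apical=decision.apical,
                n_lateral=decision.n_lateral,
                burst_date=decision.burst_day,
                cycle=cycle,
                ancestor_id=anc_id,
            )
            for gid in new_ids:
                _assign_gu_geometry(arch, gid, anc.position, params, rng)
                _update_pipe_diameters(arch, descendant_counts, gid, params)
                queue.append(gid)

        # ---- deferred mixed-inflorescence daughters -----------------------
        for bearer_id, n_daughters, apical, month in pending_mixed:
            bearer = arch.gus[bearer_id]
            year = _month_year(month, cycle, params.config.start_year)
            day = sample_burst_day(("month", year, month), rng)
            apical_ok = apical and not any(
                arch.gus[c].position == "apical" for c in arch.children[bearer_id]
            )
            n_lateral = n_daughters - (1 if apical_ok else 0)
            if not apical_ok and n_lateral == 0:
                n_lateral = 1
            new_ids = arch.add_daughters(
                bearer_id,
                apical=apical_ok,
                n_lateral=n_lateral,
                burst_date=day,
                cycle=cycle,
                ancestor_id=bearer_id,
            )
            for gid in new_ids:
                _assign_gu_geometry(arch, gid, bearer.position, params, rng)
                _update_pipe_diameters(arch, descendant_counts, gid, params)
                queue.append(gid)
        pending_mixed = []

        # ---- within-cycle vegetative automaton ----------------------------
        queue.sort(key=lambda g: (arch.gus[g].burst_date, g))
        i = 0
        while i < len(queue):
            gid = queue[i]
            i += 1
            gu = arch.gus[gid]
            anc = arch.gus[gu.ancestor_id]
            ctx = FactorContext(
                mother_burst_date=gu.burst_date.month,
                mother_position=gu.position,
                ancestor_position=anc.position,
                ancestor_fate=anc.fate,
                cycle=cycle,
            )
            decision = vegetative_burst_step(ctx, params, rng, arch, gid)
            if decision is None:
                continue
            new_ids = arch.add_daughters(
                gid,
                apical=decision.apical,
                n_lateral=decision.n_lateral,
                burst_date=decision.burst_day,
                cycle=cycle,
                ancestor_id=gu.ancestor_id,
            )
            for new_gid in new_ids:
                _assign_gu_geometry(arch, new_gid, gu.position, params, rng)
                _update_pipe_diameters(arch, descendant_counts, new_gid, params)
                queue.append(new_gid)

        # ---- flowering and fruiting on season-end terminals ---------------
        season_terminals = sorted(arch.terminal_gus(veg_end))
        cycle_fruiting: list[int] = []
        for gid in season_terminals:
            gu = arch.gus[gid]
            anc = arch.gus[gu.ancestor_id]
            ctx = FactorContext(
                mother_burst_date=gu.burst_date.month,
                mother_position=gu.position,
                ancestor_position=anc.position,
                ancestor_fate=anc.fate,
                cycle=cycle,
            )
            apical_taken = any(
                arch.inflorescences[iid].position == "apical" for iid in arch.inflos_of[gid]
            )
            flowering = flowering_step(ctx, params, rng, arch, gid)
            if flowering is None:
                gu.fate = "quiescent"
                continue
            if flowering.kind == "mixed" and apical_taken:
                # the apical bud was consumed by an earlier cycle's
                # inflorescence; a mixed (always apical) one cannot form
                gu.fate = "quiescent"
                continue
            burst = _inflo_burst_from_bloom(flowering.bloom_day, weather, params)
            for k in range(flowering.n_inflorescences):
                position = (
                    "apical"
                    if (flowering.kind == "mixed" or k == 0) and not apical_taken
                    else "lateral"
                )
                iid = arch.add_inflorescence(
                    gid,
                    kind=flowering.kind,
                    position=position,
                    burst_date=burst,
                    full_bloom_date=flowering.bloom_day,
                    cycle=cycle,
                )
                geo = inflorescence_geometry(params, rng)
                arch.inflorescences[iid].axis_length = geo["axis_length"]
                arch.inflorescences[iid].n_second_order_axes = geo["n_second_order_axes"]

            if flowering.kind == "mixed":
                gu.fate = "flowering"
                # mixed inflorescences may produce daughter GUs in Dec-Feb
                if params.table("mixed_burst").lookup().sample(rng):
                    n = int(params.table("mixed_n_daughters").lookup().sample(rng))
                    apical = bool(params.table("mixed_has_apical").lookup().sample(rng))
                    month = int(params.table("mixed_burst_month").lookup().sample(rng))
                    pending_mixed.append((gid, n, apical, month))
                continue

            n_fruits = fruiting_step(
                ctx, flowering.bloom_day, flowering.n_inflorescences, params, rng, arch, gid
            )
            if n_fruits is None:
                gu.fate = "flowering"
            else:
                gu.fate = "fruiting"
                arch.add_fruits(gid, n_fruits, flowering.bloom_day, cycle)
                cycle_fruiting.append(gid)

        for gid in season_terminals:
            arch.gus[gid].fate_history[cycle] = arch.gus[gid].fate

        # ---- fruit growth on the cycle's fruiting branches -----------------
        if grow_fruits and weather is not None and cycle_fruiting:
            _grow_cycle_fruits(arch, cycle, weather, params, rng)

    return arch


def _grow_cycle_fruits(arch: TreeArchitecture, cycle: int, weather: WeatherSeries,
                       params: ParameterSet, rng: np.random.Generator) -> None:
    from .applications import identify_fruiting_branches

    model = get_expansion_model(params.config.expansion_model)
    branches = identify_fruiting_branches(arch, params.config.fruiting_branch_size, cycle=cycle)
    gap_list = params.config.gap_fractions
    for branch in branches:
        fruit_ids = sorted(
            fid
            for fid, fr in arch.fruits.items()
            if fr.cycle == cycle and fr.bearer_id in branch.fruiting_gu_ids
        )
        if not fruit_ids:
            continue
        bloom = min(arch.fruits[fid].bloom_date for fid in fruit_ids)
        ctx = FruitingBranchContext(
            n_leaves=max(branch.n_leaves, 0),
            n_fruits=len(fruit_ids),
            gap_fraction=float(gap_list[int(rng.integers(0, len(gap_list)))]),
            reserve=params.config.initial_reserve_g,
        )
        try:
            states, harvest = simulate_branch_fruit_growth(
                bloom, ctx, weather, params, rng, model=model
            )
        except ValueError:
            continue  # weather does not cover the fruiting window
        for fid, state in zip(fruit_ids, states):
            fr = arch.fruits[fid]
            fr.dry_mass = state.dry_mass
            fr.fresh_mass = state.fresh_mass
            fr.harvest_date = harvest
            arch.events.append((fid, "harvest", harvest))


def simulate_trees(
    ancestor_sets: Sequence[Sequence[AncestorSpec]],
    weather: Optional[WeatherSeries],
    params: ParameterSet,
    n_cycles: int,
    seed: int,
    grow_fruits: bool = True,
) -> list[TreeArchitecture]:
    """Simulate several trees with one independent RNG stream per tree.

    Tree ``i`` uses ``default_rng(seed + i)``, so adding trees never
    perturbs the realizations of earlier trees.
    """
    out = []
    for i, ancestors in enumerate(ancestor_sets):
        rng = np.random.default_rng(seed + i)
        out.append(run_growing_cycles(ancestors, weather, params, n_cycles, rng, grow_fruits))
    return out
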