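"""Two-phase fruit growth and fruit shape allometry.

Phase 1 (cell division) runs for 352.7 degree-days after full bloom with a
16 degree C base temperature; at its end each fruit receives a stochastic
dry mass drawn from the published two-component Gaussian mixture
0.97 N(13.9, 4.1^2) + 0.03 N(29.2, 0.66^2) and the corresponding fresh mass
Mf = 23.647 Md^0.6182.

Phase 2 (cell expansion) is delegated to a pluggable :class:`ExpansionModel`.
The full carbon- and water-balance ecophysiological model operating at the
fruiting-branch scale is out of scope here; the default
:class:`SourceSinkExpansionModel` is an explicit reduced stand-in exposing
the same interface and the same qualitative behaviour: daily dry-mass demand
follows a logistic curve in thermal time toward a potential mass, supply is
proportional to the branch's leaf number scaled by its light environment
(gap fraction) plus a finite initial reserve, and realized growth is
demand-limited when sources are ample and supply-limited otherwise — so
final mass saturates with the branch leaf:fruit ratio.  Fruiting branches
are treated as autonomous for carbon.

Growing fruits are ellipsoids whose height and two diameters are power laws
of fresh mass.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .parameters import AllometryParams, ParameterSet

__all__ = [
    "FruitingBranchContext",
    "FruitState",
    "ExpansionModel",
    "SourceSinkExpansionModel",
    "cell_division_end",
    "initial_dry_mass",
    "fresh_from_dry",
    "fruit_shape",
    "simulate_branch_fruit_growth",
    "get_expansion_model",
]


@dataclass
class FruitingBranchContext:
    """Carbon sources and sinks of one autonomous fruiting branch."""

    n_leaves: int
    n_fruits: int
    gap_fraction: float = 0.6
    reserve: float = 15.0  # g assimilate available at start of expansion

    def __post_init__(self) -> None:
        if self.n_fruits < 1:
            raise ValueError("a fruiting branch carries at least one fruit")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap fraction must lie in [0, 1]")

    @property
    def leaf_fruit_ratio(self) -> float:
        return self.n_leaves / self.n_fruits


@dataclass
class FruitState:
    dry_mass: float
    fresh_mass: float
    tts: float = 0.0  # degree-days since expansion start (base 16)


def cell_division_end(bloom_date: dt.date, weather, *, base_t: float = 16.0,
                      threshold: float = 352.7) -> dt.date:
    """First day on which the post-bloom thermal sum reaches the threshold.

    Accumulation starts the day after full bloom, so at a constant daily
    increment i the phase ends ceil(threshold / i) days after bloom.
    """
    total = 0.0
    day = bloom_date + dt.timedelta(days=1)
    while weather.covers(day):
        total += max(0.0, weather.temperature(day) - base_t)
        if total >= threshold:
            return day
        day += dt.timedelta(days=1)
    raise ValueError(
        f"weather series exhausted before cell division completed "
        f"(reached {total:.1f} of {threshold} degree-days from {bloom_date})"
    )


def initial_dry_mass(params: ParameterSet, rng: np.random.Generator) -> tuple[float, int]:
    """End-of-cell-division dry mass draw; returns (mass g, component index).

    Component 1 is the high-mean (29.2 g) component.  Non-positive draws are
    resampled inside the mixture sampler.
    """
    spec = params.table("fruit_initial_dry_mass").lookup()
    return spec.sample_with_label(rng)


def fresh_from_dry(dry_mass: float, allometry: AllometryParams | None = None) -> float:
    """Allometric fresh mass (g) from dry mass (g)."""
    if dry_mass <= 0:
        raise ValueError("dry mass must be > 0")
    a, b = (allometry or AllometryParams()).fresh_from_dry
    return a * dry_mass**b


def fruit_shape(fresh_mass: float, allometry: AllometryParams | None = None) -> dict[str, float]:
    """Ellipsoid dimensions (cm) of a growing fruit from its fresh mass."""
    if fresh_mass <= 0:
        raise ValueError("fresh mass must be > 0")
    al = allometry or AllometryParams()
    return {
        "height": al.fruit_height[0] * fresh_mass ** al.fruit_height[1],
        "largest_diameter": al.fruit_large_diameter[0] * fresh_mass ** al.fruit_large_diameter[1],
        "smallest_diameter": al.fruit_small_diameter[0] * fresh_mass ** al.fruit_small_diameter[1],
    }


# ---------------------------------------------------------------------------
# Expansion models
# ---------------------------------------------------------------------------

class ExpansionModel(Protocol):
    """Daily cell-expansion interface.

    ``daily_step`` receives the fruits of one branch (equal treatment of the
    shared context) and the day's mean temperature, updates the fruit states
    in place, and returns the total dry-mass gain allocated.
    A full carbon/water ecophysiological model can be dropped in behind this
    interface and selected by name through the configuration.
    """

    def daily_step(
        self,
        fruits: list[FruitState],
        branch: FruitingBranchContext,
        t_mean: float,
    ) -> float: ...


@dataclass
class SourceSinkExpansionModel:
    """Reduced source-sink expansion model (the packaged default).

    Parameters
    ----------
    potential_dry_mass:
        Asymptotic dry mass (g) a fully supplied fruit grows toward.  The
        default puts the corresponding fresh-mass ceiling near 440 g.
    assimilate_per_leaf:
        Daily supply (g dry-mass equivalent) contributed by one leaf under a
        fully open sky; scaled by the branch gap fraction.
    base_t, duration_tts:
        Thermal-time clock of the demand curve (base 16 degrees C, matching
        the cell-division phase; the logistic spans ``duration_tts``
        degree-days with its inflexion at the midpoint).
    slope_tts:
        Slope of the logistic demand curve in degree-days.
    """

    potential_dry_mass: float = 113.0
    assimilate_per_leaf: float = 0.05
    base_t: float = 16.0
    duration_tts: float = 900.0
    slope_tts: float = 120.0

    def _demand_fraction(self, tts: float) -> float:
        return 1.0 / (1.0 + math.exp(-(tts - self.duration_tts / 2.0) / self.slope_tts))

    def daily_step(
        self,
        fruits: list[FruitState],
        branch: FruitingBranchContext,
        t_mean: float,
    ) -> float:
        inc = max(0.0, t_mean - self.base_t)
        demands = []
        for fr in fruits:
            before = self._demand_fraction(fr.tts)
            after = self._demand_fraction(fr.tts + inc)
            headroom = max(0.0, self.potential_dry_mass - fr.dry_mass)
            demands.append(min(headroom, self.potential_dry_mass * (after - before)))
        total_demand = sum(demands)
        photosynthesis = branch.n_leaves * self.assimilate_per_leaf * branch.gap_fraction
        supply = photosynthesis
        if supply < total_demand and branch.reserve > 0.0:
            draw = min(branch.reserve, total_demand - supply)
            branch.reserve -= draw
            supply += draw
        assert branch.reserve >= -1e-12, "reserve went negative"
        ratio = 1.0 if total_demand <= 0 else min(1.0, supply / total_demand)
        allocated = 0.0
        for fr, demand in zip(fruits, demands):
            gain = demand * ratio
            fr.dry_mass += gain
            fr.fresh_mass = max(fr.fresh_mass, fresh_from_dry(fr.dry_mass))
            fr.tts += inc
            allocated += gain
        return allocated


_MODELS = {"source-sink": SourceSinkExpansionModel}


def get_expansion_model(name: str, **kwargs) -> ExpansionModel:
    try:
        return _MODELS[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown expansion model {name!r}; available: {sorted(_MODELS)}")


def register_expansion_model(name: str, factory) -> None:
    _MODELS[name] = factory


def simulate_branch_fruit_growth(
    bloom_date: dt.date,
    branch: FruitingBranchContext,
    weather,
    params: ParameterSet,
    rng: np.random.Generator,
    model: ExpansionModel | None = None,
    max_days: int | None = None,
) -> tuple[list[FruitState], dt.date]:
    """Grow all fruits of one branch from bloom to harvest.

    Returns the final fruit states and the harvest date (expansion window of
    ``config.expansion_duration_days`` after the end of cell division,
    truncated at the end of the weather series).
    """
    model = model or get_expansion_model(params.config.expansion_model)
    div_end = cell_division_end(
        bloom_date,
        weather,
        base_t=params.thermal.fruit_cell_division_base,
        threshold=params.thermal.fruit_cell_division_tts,
    )
    fruits = []
    for _ in range(branch.n_fruits):
        md, _comp = initial_dry_mass(params, rng)
        fruits.append(FruitState(dry_mass=md, fresh_mass=fresh_from_dry(md)))
    n_days = max_days if max_days is not None else params.config.expansion_duration_days
    day = div_end + dt.timedelta(days=1)
    harvest = div_end
    for _ in range(n_days):
        if not weather.covers(day):
            break
        model.daily_step(fruits, branch, weather.temperature(day))
        harvest = day
        day += dt.timedelta(days=1)
    return fruits, harvest
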