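"""Thermal-time phenology, sigmoidal organ growth and static geometry.

Development of growth units (GUs) and inflorescences is driven by thermal
time: every day contributes max(0, T_mean - T_base) degree-days, and a
phenological stage or a growth duration completes when its accumulated sum
reaches a stage-specific threshold.  Stage schedules and growth-model
constants come from :class:`~vmango.parameters.ThermalTimeParams`.

Organ elongation follows a logistic curve in thermal time,

    l(tts) = L / (1 + exp(-(tts - t_ip) / B)),

with the inflexion t_ip at half the growth-duration threshold for GU axes
and leaves, and a fitted constant for inflorescence axes.  The slope B is
constant except for leaves, where B = L / (0.06 L - 0.08) depends on the
final leaf length.

Static geometry (axis length, leaf number and sizes, internode profile,
basal diameter) is sampled at burst from the parameterized distributions and
allometries; during growth every linear dimension is scaled by the ratio of
current to final axis length.  Secondary growth follows the pipe model:
d = 0.88 nbd^0.41 with nbd the number of descendant GUs, applied each time a
descendant appears and never shrinking an existing diameter.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .parameters import (
    AllometryParams,
    GrowthModelParams,
    ParameterError,
    ParameterSet,
    ThermalTimeParams,
)

__all__ = [
    "thermal_increment",
    "PhenologyTracker",
    "stage_of",
    "stage_intervals",
    "sigmoid_length",
    "leaf_count",
    "gu_geometry",
    "inflorescence_geometry",
    "pipe_update_diameter",
    "GrowthState",
    "grow_day",
]


def thermal_increment(t_mean: float, base_t: float) -> float:
    """Daily degree-day increment: max(0, T_mean - T_base)."""
    return max(0.0, t_mean - base_t)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Phenological stages
# ---------------------------------------------------------------------------

class PhenologyTracker:
    """Sequential stage accumulator for one entity.

    Stages run in order; each accumulates degree-days above its own base
    temperature from its onset.  A stage completes on the first day its
    accumulator reaches its threshold; the next stage starts the following
    day (the remainder of the crossing day's increment is not carried over,
    since increments under different base temperatures are not commensurate).
    After the last scheduled stage the entity sits in the terminal stage
    (H for GUs, G for inflorescences).
    """

    def __init__(self, kind: str, thermal: ThermalTimeParams) -> None:
        self.kind = kind
        self.stages = [s for s in thermal.stages_for(kind) if s.tts_threshold > 0]
        self.terminal = thermal.terminal_stage(kind)
        self.idx = 0
        self.accumulator = 0.0

    @property
    def stage(self) -> str:
        if self.idx >= len(self.stages):
            return self.terminal
        return self.stages[self.idx].name

    @property
    def completed(self) -> bool:
        return self.idx >= len(self.stages)

    def advance_day(self, t_mean: float) -> str:
        """Feed one day's mean temperature; return the stage in progress."""
        if not self.completed:
            st = self.stages[self.idx]
            self.accumulator += thermal_increment(t_mean, st.base_T)
            if self.accumulator >= st.tts_threshold:
                self.idx += 1
                self.accumulator = 0.0
        return self.stage


def stage_of(kind: str, daily_temps: Sequence[float], thermal: ThermalTimeParams) -> str:
    """Stage reached after the given sequence of daily mean temperatures."""
    tracker = PhenologyTracker(kind, thermal)
    stage = tracker.stage
    for t in daily_temps:
        stage = tracker.advance_day(t)
    return stage


def stage_intervals(
    kind: str,
    burst_date: dt.date,
    weather,
    thermal: ThermalTimeParams,
) -> list[tuple[str, dt.date, dt.date]]:
    """(stage, first_day, last_day) intervals from burst to stage completion.

    ``weather`` is any mapping supporting ``temperature(date)``.  The
    terminal stage's interval is open-ended and capped at the last available
    weather day.
    """
    tracker = PhenologyTracker(kind, thermal)
    intervals: list[tuple[str, dt.date, dt.date]] = []
    day = burst_date
    current = tracker.stage
    start = day
    last = weather.end
    while day <= last:
        stage_after = tracker.advance_day(weather.temperature(day))
        if stage_after != current:
            intervals.append((current, start, day))
            current = stage_after
            start = day + dt.timedelta(days=1)
            if tracker.completed:
                break
        day += dt.timedelta(days=1)
    intervals.append((current, start, last))
    return intervals


# ---------------------------------------------------------------------------
# Sigmoidal growth
# ---------------------------------------------------------------------------

def sigmoid_length(final_length: float, tts: float, t_ip: float, slope: float) -> float:
    """Logistic organ length at thermal time ``tts``."""
    if final_length <= 0:
        raise ValueError("final length must be > 0")
    if slope <= 0:
        raise ValueError("slope parameter B must be > 0")
    return final_length / (1.0 + math.exp(-(tts - t_ip) / slope))


# ---------------------------------------------------------------------------
# Static geometry
# ---------------------------------------------------------------------------

def leaf_count(axis_length: float, position: str, allometry: AllometryParams, *, rounded: bool = True):
    """Leaf number from axis length; linear map, rounded half-up, floor 1."""
    if position == "apical":
        a, b = allometry.leaf_number_apical
    elif position == "lateral":
        a, b = allometry.leaf_number_lateral
    else:
        raise ParameterError(f"unknown GU position {position!r}")
    raw = a * axis_length + b
    if not rounded:
        return raw
    return max(1, _round_half_up(raw))


def _internode_profile(
    axis_length: float,
    first_internode: float,
    n: int,
    decay: float,
) -> list[float]:
    """Final internode lengths summing exactly to the axis length.

    The first (most basal) internode has its own model; the remaining n-1
    internodes decay exponentially at the published rate along the
    normalized position u, with u = 0 at the second internode and u = 1 at
    the nth.  The profile is renormalized so the internodes sum to L.
    """
    first = min(first_internode, axis_length)
    if n <= 1:
        return [axis_length]
    remaining = axis_length - first
    m = n - 1
    if m == 1:
        weights = np.array([1.0])
    else:
        u = np.arange(m) / (m - 1)
        weights = np.exp(-decay * u)
    weights = weights / weights.sum()
    return [first] + list(weights * remaining)


def gu_geometry(
    position: str,
    mother_position: str,
    params: ParameterSet,
    rng: np.random.Generator,
) -> dict:
    """Sample the full static geometry of a GU at burst.

    Returns final dimensions: axis length L, leaf number, individual leaf
    lengths (common length for all leaves except the distal one at 48 % and
    the penultimate at 62 % of it), leaf widths and areas, internode
    lengths (first internode gamma-distributed for apical GUs, linear in L
    for lateral ones), basal diameter, and the 144-degree phyllotaxy.
    """
    al = params.allometry
    L = params.table("gu_axis_length").lookup(
        position=position, mother_position=mother_position
    ).sample(rng)
    L = max(L, 1.0)  # Gaussian tail guard: lengths are strictly positive

    n = leaf_count(L, position, al)

    common_leaf = params.table("leaf_length").lookup(position=position).sample(rng)
    common_leaf = max(common_leaf, 1.0)
    leaf_lengths = [common_leaf] * n
    if n >= 1:
        leaf_lengths[-1] = common_leaf * al.distal_leaf_factor
    if n >= 2:
        leaf_lengths[-2] = common_leaf * al.penultimate_leaf_factor
    leaf_widths = [al.leaf_width_ratio * l for l in leaf_lengths]
    leaf_areas = [al.leaf_area_coef * l**2 for l in leaf_lengths]

    if position == "apical":
        first = params.table("first_internode_apical").lookup().sample(rng)
    else:
        a, b = al.first_internode_lateral
        first = a * L + b
    internodes = _internode_profile(L, first, n, al.internode_decay)

    da, db = al.diameter_vs_length
    diameter = rng.normal(da * L + db, al.diameter_sd)
    diameter = max(diameter, 0.05)

    return {
        "axis_length": float(L),
        "n_leaves": int(n),
        "common_leaf_length": float(common_leaf),
        "leaf_lengths": [float(x) for x in leaf_lengths],
        "leaf_widths": [float(x) for x in leaf_widths],
        "leaf_areas": [float(x) for x in leaf_areas],
        "internode_lengths": [float(x) for x in internodes],
        "basal_diameter": float(diameter),
        "phyllotaxy_deg": al.phyllotaxy_deg,
    }


def inflorescence_geometry(params: ParameterSet, rng: np.random.Generator) -> dict:
    """Sample inflorescence main-axis length and second-order axis profile."""
    al = params.allometry
    L = params.table("inflorescence_axis_length").lookup().sample(rng)
    L = max(L, 1.0)
    n2 = max(1, _round_half_up(al.second_order_axes_per_cm * L))
    a, b = al.second_order_length
    lengths = []
    for k in range(n2):
        v = k / (n2 - 1) if n2 > 1 else 0.0
        lengths.append(max(0.0, (a * L - b) * (1.0 - v)))
    return {
        "axis_length": float(L),
        "n_second_order_axes": int(n2),
        "second_order_lengths": [float(x) for x in lengths],
    }


def pipe_update_diameter(n_descendants: int, allometry: AllometryParams | None = None) -> float:
    """Pipe-model diameter (cm) of a GU carrying ``n_descendants`` GUs."""
    if n_descendants < 1:
        raise ValueError("pipe model applies only once a descendant exists")
    al = allometry or AllometryParams()
    a, b = al.pipe_model
    return a * n_descendants**b


# ---------------------------------------------------------------------------
# Daily growth state
# ---------------------------------------------------------------------------

@dataclass
class GrowthState:
    """Daily elongation state of one organ (GU axis, leaf or inflo axis)."""

    kind: str                      # "gu_axis" | "leaf" | "inflorescence_axis"
    final_length: float
    model: GrowthModelParams
    tts: float = 0.0
    length: float = 0.0
    completed: bool = False

    def __post_init__(self) -> None:
        self.length = self.current_length()

    def current_length(self) -> float:
        return sigmoid_length(
            self.final_length,
            self.tts,
            self.model.inflexion(),
            self.model.slope(self.final_length),
        )


def grow_day(state: GrowthState, t_mean: float) -> GrowthState:
    """Advance one day of growth; length and tts are nondecreasing."""
    if state.completed:
        return state
    inc = thermal_increment(t_mean, state.model.base_T)
    state.tts += inc
    state.length = max(state.length, state.current_length())
    if state.tts >= state.model.tts_threshold:
        state.completed = True
    return state


def growth_model_for(kind: str, thermal: ThermalTimeParams) -> GrowthModelParams:
    if kind == "gu_axis":
        return thermal.gu_axis_growth
    if kind == "leaf":
        return thermal.leaf_growth
    if kind == "inflorescence_axis":
        return thermal.inflo_axis_growth
    raise ParameterError(f"unknown growth-model kind {kind!r}")
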