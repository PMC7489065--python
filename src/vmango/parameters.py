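"""Parameterization of the mango architectural model.

The simulator is driven entirely by a :class:`ParameterSet`: a collection of
probability tables (one per elementary developmental process, keyed by
combinations of structural and temporal factor levels), thermal-time
constants for phenology and organ growth, allometric constants for organ
geometry, and a simulation configuration (cycle calendar, fruiting-branch
size, light environments).

The packaged defaults (:func:`default_parameterization`) transcribe the
published Cogshall parameterization: the printed process probabilities
(e.g. P=0.80 for within-cycle burst of August-December mothers, P=0.98 for
an apical daughter, P=0.06 for mixed inflorescences, the 0.40/0.20/0
fruit-set probabilities by bloom window), the Gaussian/Gamma/mixture
distributions of organ dimensions, and the thermal-time tables for
phenological stages and sigmoidal organ growth.  Ordinal-multinomial tables
for burst months and bloom weeks are published only as qualitative patterns;
the defaults encode those patterns and are meant to be replaced by users
with locally fitted tables (see the calibration module).

Parameter sets round-trip losslessly through a plain-text directory layout:
``config.json`` for scalar constants and ``tables/<process_id>.csv`` for the
probability tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DistributionSpec",
    "ProbabilityTable",
    "ThermalStage",
    "GrowthModelParams",
    "ThermalTimeParams",
    "AllometryParams",
    "SimulationConfig",
    "ParameterSet",
    "ParameterError",
    "ValidationError",
    "default_parameterization",
    "load_parameterization",
    "save_parameterization",
    "truncated_poisson_rate_for_mean",
    "truncated_poisson_mean",
    "PROCESS_IDS",
]

_ATOL = 1e-9

# Months of the growing-cycle periods, in within-cycle order.  Vegetative
# growth runs August-May (the calibration trees produced GUs from August on,
# with the September-May window quoted for the bulk of it), flowering
# July-September, harvest December-February.
VEGETATIVE_MONTHS: tuple[int, ...] = (8, 9, 10, 11, 12, 1, 2, 3, 4, 5)
FLOWERING_MONTHS: tuple[int, ...] = (7, 8, 9)
HARVEST_MONTHS: tuple[int, ...] = (12, 1, 2)

POSITIONS = ("apical", "lateral")
FATES = ("quiescent", "flowering", "fruiting")
BLOOM_WINDOWS = ("early", "mid", "late")

#: every process id the automata and geometry samplers query.
PROCESS_IDS: tuple[str, ...] = (
    "vegetative_burst_within",
    "has_apical_daughter",
    "has_lateral_daughters",
    "n_lateral_daughters",
    "burst_month",
    "vegetative_burst_between",
    "has_apical_daughter_between",
    "has_lateral_daughters_between",
    "n_lateral_daughters_between",
    "burst_month_between",
    "is_mixed_inflorescence",
    "flowering",
    "n_inflorescences",
    "bloom_week",
    "fruiting",
    "n_fruits",
    "mixed_burst",
    "mixed_n_daughters",
    "mixed_has_apical",
    "mixed_burst_month",
    "gu_axis_length",
    "leaf_length",
    "first_internode_apical",
    "inflorescence_axis_length",
    "fruit_initial_dry_mass",
)

# How factor levels are cast back from their CSV string form.
_FACTOR_CASTS = {
    "mother_burst_date": int,
    "ancestor_burst_date": int,
    "cycle": int,
    "mother_position": str,
    "ancestor_position": str,
    "ancestor_fate": str,
    "bloom_window": str,
    "n_inflorescences_class": str,
}


class ParameterError(Exception):
    """Malformed parameter file (parse-level failure)."""


class ValidationError(Exception):
    """A parameter value violates an invariant."""


# ---------------------------------------------------------------------------
# Truncated-Poisson helpers
# ---------------------------------------------------------------------------

def truncated_poisson_mean(rate: float) -> float:
    """Conditional mean of a zero-truncated Poisson with the given rate."""
    if rate <= 0.0:
        return 1.0
    return rate / (1.0 - math.exp(-rate))


def truncated_poisson_rate_for_mean(mean: float) -> float:
    """Rate lambda such that E[X | X>=1] equals ``mean`` for X ~ Poisson(lambda).

    A conditional mean of exactly 1 corresponds to the degenerate limit
    lambda -> 0 (the count is then always 1); it is encoded as rate 0.
    """
    if mean < 1.0 - _ATOL:
        raise ValidationError(f"truncated-Poisson conditional mean must be >= 1, got {mean}")
    if mean <= 1.0 + 1e-9:
        return 0.0
    return float(optimize.brentq(lambda lam: truncated_poisson_mean(lam) - mean, 1e-12, mean))


# ---------------------------------------------------------------------------
# DistributionSpec
# ---------------------------------------------------------------------------

_FAMILIES = (
    "gaussian",
    "gamma",
    "poisson-truncated",
    "ordinal-multinomial",
    "bernoulli",
    "mixture-of-gaussians",
)


@dataclass(frozen=True)
class DistributionSpec:
    """A named distribution family with validated parameters.

    Parameters are stored in ``params``:

    - gaussian: ``mean``, ``sd``
    - gamma: ``shape``, ``scale``
    - poisson-truncated: ``rate`` (0 encodes the degenerate count of 1)
    - bernoulli: ``p``
    - mixture-of-gaussians: ``weights``, ``means``, ``sds`` (lists)
    - ordinal-multinomial: ``categories``, ``probs`` (lists; categories are
      ordered levels such as calendar months or week indices)
    """

    family: str
    params: Mapping[str, Any]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        p = dict(self.params)
        object.__setattr__(self, "params", p)
        self.validate()

    def validate(self) -> None:
        p = self.params
        f = self.family
        try:
            if f == "gaussian":
                if not p["sd"] > 0:
                    raise ValidationError(f"gaussian sd must be > 0, got {p['sd']}")
            elif f == "gamma":
                if not (p["shape"] > 0 and p["scale"] > 0):
                    raise ValidationError("gamma shape and scale must be > 0")
            elif f == "poisson-truncated":
                if p["rate"] < 0:
                    raise ValidationError("truncated-Poisson rate must be >= 0")
            elif f == "bernoulli":
                if not 0.0 <= p["p"] <= 1.0:
                    raise ValidationError(f"Bernoulli p must be in [0,1], got {p['p']}")
            elif f == "mixture-of-gaussians":
                w = np.asarray(p["weights"], dtype=float)
                sds = np.asarray(p["sds"], dtype=float)
                if not (len(w) == len(p["means"]) == len(sds)):
                    raise ValidationError("mixture component lists must have equal length")
                if abs(w.sum() - 1.0) > _ATOL:
                    raise ValidationError(f"mixture weights sum to {w.sum()}, not 1")
                if (sds <= 0).any():
                    raise ValidationError("mixture sds must be > 0")
            elif f == "ordinal-multinomial":
                probs = np.asarray(p["probs"], dtype=float)
                if len(probs) != len(p["categories"]):
                    raise ValidationError("multinomial categories and probs differ in length")
                if (probs < 0).any():
                    raise ValidationError("multinomial probabilities must be >= 0")
                if abs(probs.sum() - 1.0) > _ATOL:
                    raise ValidationError(
                        f"multinomial probabilities sum to {probs.sum():.6f}, not 1"
                    )
        except KeyError as exc:  # missing parameter
            raise ValidationError(f"{f} spec missing parameter {exc}") from exc

    # -- sampling ----------------------------------------------------------

    def sample(self, rng: np.random.Generator) -> Any:
        f = self.family
        p = self.params
        if f == "gaussian":
            return float(rng.normal(p["mean"], p["sd"]))
        if f == "gamma":
            return float(rng.gamma(p["shape"], p["scale"]))
        if f == "bernoulli":
            return bool(rng.random() < p["p"])
        if f == "poisson-truncated":
            rate = p["rate"]
            if rate <= 0.0:
                return 1
            # inverse-CDF restricted to k >= 1
            u = rng.uniform(stats.poisson.cdf(0, rate), 1.0)
            return int(stats.poisson.ppf(u, rate))
        if f == "mixture-of-gaussians":
            value, _ = self.sample_with_label(rng)
            return value
        if f == "ordinal-multinomial":
            cum = np.cumsum(p["probs"])
            idx = int(np.searchsorted(cum, rng.random(), side="right"))
            idx = min(idx, len(p["categories"]) - 1)
            return p["categories"][idx]
        raise AssertionError(f)

    def sample_with_label(self, rng: np.random.Generator) -> tuple[float, int]:
        """Mixture draw returning ``(value, component_index)``.

        Non-positive draws are resampled (mass positivity; the Gaussian
        components have small negative tails).
        """
        if self.family != "mixture-of-gaussians":
            raise ValidationError("sample_with_label applies to mixture-of-gaussians only")
        p = self.params
        weights = np.asarray(p["weights"], dtype=float)
        cum = np.cumsum(weights)
        while True:
            comp = int(np.searchsorted(cum, rng.random(), side="right"))
            comp = min(comp, len(weights) - 1)
            value = float(rng.normal(p["means"][comp], p["sds"][comp]))
            if value > 0.0:
                return value, comp

    def mean(self) -> float:
        """Analytic mean (used by the ablation machinery)."""
        f, p = self.family, self.params
        if f == "gaussian":
            return float(p["mean"])
        if f == "gamma":
            return float(p["shape"] * p["scale"])
        if f == "bernoulli":
            return float(p["p"])
        if f == "poisson-truncated":
            return truncated_poisson_mean(p["rate"])
        if f == "mixture-of-gaussians":
            return float(np.dot(p["weights"], p["means"]))
        raise ValidationError(f"no scalar mean for family {f}")

    # -- CSV (de)serialization --------------------------------------------

    def to_flat(self) -> dict[str, str]:
        out = {"family": self.family}
        for key, value in self.params.items():
            if isinstance(value, (list, tuple, np.ndarray)):
                out[f"param:{key}"] = json.dumps(list(value))
            else:
                out[f"param:{key}"] = json.dumps(value)
        return out

    @classmethod
    def from_flat(cls, row: Mapping[str, str]) -> "DistributionSpec":
        params: dict[str, Any] = {}
        for key, raw in row.items():
            if key.startswith("param:") and raw not in ("", None):
                params[key[len("param:"):]] = json.loads(raw)
        return cls(family=row["family"], params=params)


# ---------------------------------------------------------------------------
# ProbabilityTable
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityTable:
    """Per-process parameter lookup keyed by factor-level combinations.

    ``rows`` maps a tuple of factor levels (ordered as ``factors``) to a
    :class:`DistributionSpec`.  The wildcard level ``"*"`` matches any level
    of its factor; when several rows match a query the most specific one
    (fewest wildcards) wins, and validation rejects ambiguous ties.
    """

    process_id: str
    factors: tuple[str, ...]
    rows: dict[tuple, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.validate()

    def validate(self) -> None:
        for key, spec in self.rows.items():
            if len(key) != len(self.factors):
                raise ValidationError(
                    f"table {self.process_id}: row key {key} does not match "
                    f"factors {self.factors}"
                )
            if not isinstance(spec, DistributionSpec):
                raise ValidationError(f"table {self.process_id}: row {key} is not a DistributionSpec")
            spec.validate()

    def lookup(self, **levels: Any) -> DistributionSpec:
        key = tuple(levels[f] for f in self.factors)
        if key in self.rows:
            return self.rows[key]
        matches = []
        for rkey, spec in self.rows.items():
            if all(r == "*" or r == q for r, q in zip(rkey, key)):
                matches.append((sum(r == "*" for r in rkey), rkey, spec))
        if not matches:
            raise ParameterError(
                f"table {self.process_id}: no row for factor combination "
                f"{dict(zip(self.factors, key))}"
            )
        matches.sort(key=lambda m: m[0])
        if len(matches) > 1 and matches[0][0] == matches[1][0]:
            raise ValidationError(
                f"table {self.process_id}: ambiguous rows for {key}: "
                f"{matches[0][1]} and {matches[1][1]}"
            )
        return matches[0][2]

    # -- CSV ----------------------------------------------------------------

    def to_records(self) -> list[dict[str, str]]:
        records = []
        for key, spec in sorted(self.rows.items(), key=lambda kv: tuple(map(str, kv[0]))):
            rec: dict[str, str] = {"process_id": self.process_id}
            for i, fname in enumerate(self.factors):
                rec[f"factor:{fname}"] = str(key[i])
            rec.update(spec.to_flat())
            records.append(rec)
        return records

    @classmethod
    def from_records(cls, process_id: str, records: Sequence[Mapping[str, str]]) -> "ProbabilityTable":
        if not records:
            raise ParameterError(f"table {process_id}: empty")
        factor_cols = [c for c in records[0].keys() if c.startswith("factor:")]
        factors = tuple(c[len("factor:"):] for c in factor_cols)
        rows: dict[tuple, DistributionSpec] = {}
        for rec in records:
            key = []
            for fname in factors:
                raw = str(rec[f"factor:{fname}"])
                if raw == "*":
                    key.append("*")
                else:
                    key.append(_FACTOR_CASTS.get(fname, str)(raw))
            rows[tuple(key)] = DistributionSpec.from_flat(rec)
        return cls(process_id=process_id, factors=factors, rows=rows)


# ---------------------------------------------------------------------------
# Thermal time
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalStage:
    name: str
    base_T: float          # degrees C
    tts_threshold: float   # degree-days to complete the stage

    def __post_init__(self) -> None:
        if self.tts_threshold < 0:
            raise ValidationError(f"stage {self.name}: negative threshold")


@dataclass(frozen=True)
class GrowthModelParams:
    """Sigmoidal growth-model constants for one organ type.

    ``t_ip`` is the thermal time of maximum growth rate; ``None`` means "half
    of the growth-duration threshold" (the rule holding for GU axes and
    leaves).  ``B`` is the slope constant; ``None`` selects the leaf rule
    B = L / (0.06 L - 0.08), which depends on the final length.
    """

    base_T: float
    tts_threshold: float
    t_ip: float | None
    B: float | None

    def __post_init__(self) -> None:
        if self.tts_threshold <= 0:
            raise ValidationError("growth duration threshold must be > 0")
        if self.t_ip is not None and not (0 < self.t_ip < self.tts_threshold):
            raise ValidationError("t_ip must lie strictly inside (0, TTS_S)")

    def inflexion(self) -> float:
        return self.tts_threshold / 2.0 if self.t_ip is None else self.t_ip

    def slope(self, final_length: float) -> float:
        if self.B is not None:
            return self.B
        denom = 0.06 * final_length - 0.08
        if denom <= 0:
            raise ValidationError(f"leaf slope rule undefined for final length {final_length}")
        return final_length / denom


@dataclass
class ThermalTimeParams:
    """Phenological-stage schedules and growth-model constants.

    Stage schedules: thermal time is counted from bud burst (stage C); stage C
    itself has zero duration so stage D begins at burst, and each stage
    accumulates degree-days above its own base temperature from its onset.
    The terminal stage (H for GUs, G for inflorescences) is open-ended.
    """

    gu_stages: tuple[ThermalStage, ...]
    inflo_stages: tuple[ThermalStage, ...]
    gu_axis_growth: GrowthModelParams
    leaf_growth: GrowthModelParams
    inflo_axis_growth: GrowthModelParams
    fruit_cell_division_base: float = 16.0
    fruit_cell_division_tts: float = 352.7

    def stages_for(self, kind: str) -> tuple[ThermalStage, ...]:
        if kind == "gu":
            return self.gu_stages
        if kind == "inflorescence":
            return self.inflo_stages
        raise ParameterError(f"unknown entity kind {kind!r}")

    def terminal_stage(self, kind: str) -> str:
        return "H" if kind == "gu" else "G"

    def to_dict(self) -> dict:
        return {
            "gu_stages": [dataclasses.asdict(s) for s in self.gu_stages],
            "inflo_stages": [dataclasses.asdict(s) for s in self.inflo_stages],
            "gu_axis_growth": dataclasses.asdict(self.gu_axis_growth),
            "leaf_growth": dataclasses.asdict(self.leaf_growth),
            "inflo_axis_growth": dataclasses.asdict(self.inflo_axis_growth),
            "fruit_cell_division_base": self.fruit_cell_division_base,
            "fruit_cell_division_tts": self.fruit_cell_division_tts,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThermalTimeParams":
        return cls(
            gu_stages=tuple(ThermalStage(**s) for s in d["gu_stages"]),
            inflo_stages=tuple(ThermalStage(**s) for s in d["inflo_stages"]),
            gu_axis_growth=GrowthModelParams(**d["gu_axis_growth"]),
            leaf_growth=GrowthModelParams(**d["leaf_growth"]),
            inflo_axis_growth=GrowthModelParams(**d["inflo_axis_growth"]),
            fruit_cell_division_base=d["fruit_cell_division_base"],
            fruit_cell_division_tts=d["fruit_cell_division_tts"],
        )


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

@dataclass
class AllometryParams:
    """Deterministic allometric constants for organ geometry and shape."""

    # leaf number per axis length (pre-rounding linear maps)
    leaf_number_apical: tuple[float, float] = (0.59, 5.50)
    leaf_number_lateral: tuple[float, float] = (0.62, 0.36)
    # leaf dimensions
    leaf_width_ratio: float = 0.24
    leaf_area_coef: float = 0.18
    distal_leaf_factor: float = 1.0 - 0.52
    penultimate_leaf_factor: float = 1.0 - 0.38
    # internodes
    internode_decay: float = 2.64
    first_internode_lateral: tuple[float, float] = (0.88, 0.38)
    # basal diameter: N(a*L + b, sd^2)
    diameter_vs_length: tuple[float, float] = (0.025, 0.25)
    diameter_sd: float = 0.11
    phyllotaxy_deg: float = 144.0
    branching_angle_deg: float = 60.0
    # inflorescence
    second_order_axes_per_cm: float = 1.19
    second_order_length: tuple[float, float] = (0.69, 3.97)
    # fruit shape (ellipsoid power laws on fresh mass)
    fruit_height: tuple[float, float] = (2.23, 0.29)
    fruit_large_diameter: tuple[float, float] = (1.25, 0.32)
    fruit_small_diameter: tuple[float, float] = (0.98, 0.34)
    # fresh mass from dry mass
    fresh_from_dry: tuple[float, float] = (23.647, 0.6182)
    # pipe model: d = a * nbd^b
    pipe_model: tuple[float, float] = (0.88, 0.41)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AllometryParams":
        kwargs = {}
        for f in dataclasses.fields(cls):
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Cycle calendar and run-level knobs.

    The calendar follows the Reunion Island cropping context: vegetative
    growth August-May, flowering July-September, harvest December-February;
    successive 18-month cycles overlap.  ``start_year`` anchors cycle 1's
    vegetative period.
    """

    vegetative_months: tuple[int, ...] = VEGETATIVE_MONTHS
    flowering_months: tuple[int, ...] = FLOWERING_MONTHS
    harvest_months: tuple[int, ...] = HARVEST_MONTHS
    start_year: int = 2003
    n_cycles: int = 2
    seed: int = 1
    fruiting_branch_size: int = 3
    gap_fractions: tuple[float, ...] = (0.4, 0.6, 0.8)
    initial_reserve_g: float = 15.0
    expansion_duration_days: int = 90
    expansion_model: str = "source-sink"

    def __post_init__(self) -> None:
        if not self.vegetative_months or not self.flowering_months or not self.harvest_months:
            raise ValidationError("calendar month ranges must be non-empty")
        if self.fruiting_branch_size < 1:
            raise ValidationError("fruiting-branch size N must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    tables: dict[str, ProbabilityTable]
    thermal: ThermalTimeParams
    allometry: AllometryParams
    config: SimulationConfig

    def validate(self) -> None:
        for pid, table in self.tables.items():
            if pid not in PROCESS_IDS:
                raise ValidationError(f"unknown process_id {pid!r}")
            if table.process_id != pid:
                raise ValidationError(f"table registered as {pid} declares {table.process_id}")
            table.validate()
        missing = [pid for pid in PROCESS_IDS if pid not in self.tables]
        if missing:
            raise ValidationError(f"parameter set is missing tables for: {missing}")

    def table(self, process_id: str) -> ProbabilityTable:
        try:
            return self.tables[process_id]
        except KeyError:
            raise ParameterError(f"no table for process {process_id!r}") from None

    def copy(self) -> "ParameterSet":
        tables = {
            pid: ProbabilityTable(t.process_id, t.factors, dict(t.rows))
            for pid, t in self.tables.items()
        }
        return ParameterSet(
            tables=tables,
            thermal=self.thermal,
            allometry=self.allometry,
            config=dataclasses.replace(self.config),
        )


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

def _bernoulli(p: float) -> DistributionSpec:
    return DistributionSpec("bernoulli", {"p": p})


def _tpois_mean(mean: float) -> DistributionSpec:
    return DistributionSpec("poisson-truncated", {"rate": truncated_poisson_rate_for_mean(mean)})


def _gauss(mean: float, sd: float) -> DistributionSpec:
    return DistributionSpec("gaussian", {"mean": mean, "sd": sd})


def _multinomial(categories: Sequence, probs: Sequence[float]) -> DistributionSpec:
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    return DistributionSpec(
        "ordinal-multinomial", {"categories": list(categories), "probs": probs.tolist()}
    )


def _lagged_month_row(mother_month: int, window: Sequence[int]) -> DistributionSpec | None:
    """Burst-month distribution for daughters of a within-cycle mother.

    Daughters appear on average ~2.2 months after the mother within the
    vegetative window; weights below put that lag pattern on the months that
    remain available in the window (mass on lags of 1-4 months peaking at 2).
    """
    order = list(window)
    i = order.index(mother_month)
    later = order[i + 1:]
    if not later:
        return None
    lag_weights = {1: 0.18, 2: 0.50, 3: 0.22, 4: 0.10}
    cats, probs = [], []
    for lag, month in enumerate(later, start=1):
        cats.append(month)
        probs.append(lag_weights.get(lag, 0.02))
    return _multinomial(cats, probs)


def default_parameterization() -> ParameterSet:
    """The packaged Cogshall parameter set.

    Printed values are transcribed verbatim; tables published only as
    qualitative patterns (burst-month and bloom-week multinomials, flowering
    probabilities, fruit counts) carry documented defaults meant to be
    replaced with locally calibrated tables.
    """
    tables: dict[str, ProbabilityTable] = {}

    def add(pid: str, factors: Sequence[str], rows: Mapping[tuple, DistributionSpec]) -> None:
        tables[pid] = ProbabilityTable(pid, tuple(factors), dict(rows))

    # -- within-cycle vegetative automaton ---------------------------------
    add(
        "vegetative_burst_within",
        ["mother_burst_date"],
        {(m,): _bernoulli(0.80 if m in (8, 9, 10, 11, 12) else 0.02) for m in range(1, 13)},
    )
    add("has_apical_daughter", [], {(): _bernoulli(0.98)})
    add(
        "has_lateral_daughters",
        ["mother_position"],
        {("apical",): _bernoulli(0.66), ("lateral",): _bernoulli(0.28)},
    )
    add(
        "n_lateral_daughters",
        ["mother_position", "cycle"],
        {
            ("apical", 1): _tpois_mean(2.1),
            ("lateral", 1): _tpois_mean(1.3),
            ("apical", 2): _tpois_mean(2.3),
            ("lateral", 2): _tpois_mean(1.9),
        },
    )
    burst_rows = {}
    for m in VEGETATIVE_MONTHS:
        row = _lagged_month_row(m, VEGETATIVE_MONTHS)
        if row is not None:
            burst_rows[(m,)] = row
    # off-window mothers (June/July rest period) never query this table; the
    # automaton pre-checks month availability.
    add("burst_month", ["mother_burst_date"], burst_rows)

    # -- between-cycle vegetative automaton --------------------------------
    # The only printed between-cycle occurrence value is the deferral
    # probability P=0.73 (post-December mothers producing next cycle); it is
    # used for all ancestor fates and is user-replaceable.
    add(
        "vegetative_burst_between",
        ["ancestor_fate"],
        {(f,): _bernoulli(0.73) for f in FATES},
    )
    add(
        "has_apical_daughter_between",
        ["ancestor_fate"],
        {
            ("quiescent",): _bernoulli(0.82),
            ("flowering",): _bernoulli(0.0),
            ("fruiting",): _bernoulli(0.0),
        },
    )
    add(
        "has_lateral_daughters_between",
        ["ancestor_fate"],
        {
            ("quiescent",): _bernoulli(0.46),
            # flowering/fruiting ancestors cannot produce an apical daughter,
            # so a burst is necessarily lateral
            ("flowering",): _bernoulli(1.0),
            ("fruiting",): _bernoulli(1.0),
        },
    )
    add(
        "n_lateral_daughters_between",
        ["ancestor_fate"],
        {
            ("quiescent",): _tpois_mean(2.4),
            ("flowering",): _tpois_mean(3.4),
            ("fruiting",): _tpois_mean(4.2),
        },
    )
    # Qualitative Fig-5 patterns: quiescent ancestors flush early in the
    # vegetative season; flowering ancestors mostly, and fruiting ancestors
    # only, after harvest (February-March).
    add(
        "burst_month_between",
        ["ancestor_fate"],
        {
            ("quiescent",): _multinomial([9, 10, 11, 12, 1, 2], [0.30, 0.25, 0.18, 0.12, 0.08, 0.07]),
            ("flowering",): _multinomial([9, 10, 11, 2, 3], [0.10, 0.10, 0.10, 0.40, 0.30]),
            ("fruiting",): _multinomial([2, 3, 4], [0.50, 0.38, 0.12]),
        },
    )

    # -- flowering automaton -----------------------------------------------
    add("is_mixed_inflorescence", [], {(): _bernoulli(0.06)})
    # Flowering probabilities are not printed; defaults encode the stated
    # ordering (apical > lateral, non-fruiting ancestors > fruiting).
    add(
        "flowering",
        ["mother_position", "ancestor_fate"],
        {
            ("apical", "quiescent"): _bernoulli(0.55),
            ("apical", "flowering"): _bernoulli(0.55),
            ("apical", "fruiting"): _bernoulli(0.35),
            ("lateral", "quiescent"): _bernoulli(0.30),
            ("lateral", "flowering"): _bernoulli(0.30),
            ("lateral", "fruiting"): _bernoulli(0.18),
        },
    )
    add(
        "n_inflorescences",
        ["mother_burst_date"],
        {(m,): _tpois_mean(1.6 if m in (12, 1) else 1.0) for m in range(1, 13)},
    )
    # Week windows of the July-September flowering period, indexed 0..12 from
    # 1 July; September two-peak pattern.
    add(
        "bloom_week",
        [],
        {
            (): _multinomial(
                list(range(13)),
                [0.01, 0.01, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.16, 0.22, 0.10, 0.18, 0.11],
            )
        },
    )

    # -- fruiting automaton ------------------------------------------------
    add(
        "fruiting",
        ["bloom_window"],
        {("early",): _bernoulli(0.40), ("mid",): _bernoulli(0.20), ("late",): _bernoulli(0.0)},
    )
    add(
        "n_fruits",
        ["n_inflorescences_class"],
        {("1",): _tpois_mean(1.3), ("2+",): _tpois_mean(1.8)},
    )

    # -- mixed-inflorescence vegetative production -------------------------
    add("mixed_burst", [], {(): _bernoulli(0.53)})
    add("mixed_n_daughters", [], {(): _tpois_mean(2.3)})
    add("mixed_has_apical", [], {(): _bernoulli(0.47)})
    add("mixed_burst_month", [], {(): _multinomial([12, 1, 2], [0.40, 0.35, 0.25])})

    # -- geometry distributions --------------------------------------------
    add(
        "gu_axis_length",
        ["position", "mother_position"],
        {
            ("apical", "apical"): _gauss(18.1, 4.1),
            ("apical", "lateral"): _gauss(13.8, 4.0),
            ("lateral", "apical"): _gauss(12.6, 3.4),
            ("lateral", "lateral"): _gauss(12.6, 3.4),
        },
    )
    add(
        "leaf_length",
        ["position"],
        {("apical",): _gauss(17.1, 2.7), ("lateral",): _gauss(14.9, 2.7)},
    )
    add(
        "first_internode_apical",
        [],
        {(): DistributionSpec("gamma", {"shape": 2.0, "scale": 0.76})},
    )
    add("inflorescence_axis_length", [], {(): _gauss(23.1, 6.7)})
    add(
        "fruit_initial_dry_mass",
        [],
        {
            (): DistributionSpec(
                "mixture-of-gaussians",
                {"weights": [0.97, 0.03], "means": [13.9, 29.2], "sds": [4.1, 0.66]},
            )
        },
    )

    thermal = ThermalTimeParams(
        gu_stages=(
            ThermalStage("C", 13.4, 0.0),
            ThermalStage("D", 13.4, 38.5),
            ThermalStage("E", 13.4, 47.6),
            ThermalStage("F", 13.4, 47.4),
            ThermalStage("G", 9.8, 316.4),
        ),
        inflo_stages=(
            ThermalStage("D", 11.1, 70.5),
            ThermalStage("E", 8.7, 133.3),
            ThermalStage("F", 15.1, 230.4),
        ),
        gu_axis_growth=GrowthModelParams(base_T=9.2, tts_threshold=178.8, t_ip=89.4, B=22.4),
        leaf_growth=GrowthModelParams(base_T=10.7, tts_threshold=182.0, t_ip=91.0, B=None),
        inflo_axis_growth=GrowthModelParams(base_T=11.1, tts_threshold=346.0, t_ip=136.6, B=50.9),
    )

    ps = ParameterSet(
        tables=tables,
        thermal=thermal,
        allometry=AllometryParams(),
        config=SimulationConfig(),
    )
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# Directory (de)serialization
# ---------------------------------------------------------------------------

def save_parameterization(params: ParameterSet, path: str) -> None:
    """Write a parameter set as config.json + tables/<process_id>.csv."""
    import csv

    os.makedirs(os.path.join(path, "tables"), exist_ok=True)
    config = {
        "thermal": params.thermal.to_dict(),
        "allometry": params.allometry.to_dict(),
        "config": params.config.to_dict(),
    }
    with open(os.path.join(path, "config.json"), "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
    for pid, table in params.tables.items():
        records = table.to_records()
        cols: list[str] = []
        for rec in records:
            for c in rec:
                if c not in cols:
                    cols.append(c)
        with open(os.path.join(path, "tables", f"{pid}.csv"), "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            writer.writerows(records)


def load_parameterization(path: str) -> ParameterSet:
    """Load and validate a parameter-set directory written by
    :func:`save_parameterization`."""
    import csv

    config_path = os.path.join(path, "config.json")
    if not os.path.exists(config_path):
        raise ParameterError(f"{config_path}: file not found")
    try:
        with open(config_path) as fh:
            config = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParameterError(f"{config_path}: line {exc.lineno}: {exc.msg}") from exc

    tables: dict[str, ProbabilityTable] = {}
    tables_dir = os.path.join(path, "tables")
    if not os.path.isdir(tables_dir):
        raise ParameterError(f"{tables_dir}: directory not found")
    for fname in sorted(os.listdir(tables_dir)):
        if not fname.endswith(".csv"):
            continue
        pid = fname[:-4]
        if pid not in PROCESS_IDS:
            raise ValidationError(f"{fname}: unknown process_id {pid!r}")
        fpath = os.path.join(tables_dir, fname)
        with open(fpath, newline="") as fh:
            try:
                records = list(csv.DictReader(fh))
            except csv.Error as exc:
                raise ParameterError(f"{fpath}: {exc}") from exc
        try:
            tables[pid] = ProbabilityTable.from_records(pid, records)
        except (ValidationError, ParameterError) as exc:
            raise type(exc)(f"table {pid}: {exc}") from exc

    ps = ParameterSet(
        tables=tables,
        thermal=ThermalTimeParams.from_dict(config["thermal"]),
        allometry=AllometryParams.from_dict(config["allometry"]),
        config=SimulationConfig.from_dict(config["config"]),
    )
    ps.validate()
    return ps
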