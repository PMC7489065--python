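"""Synthetic simulation inputs: daily weather calendars and ancestor GUs.

The simulator needs a daily mean-temperature series and an initial
population of ancestor growth units (terminal GUs of the previous cycle,
each with a position, a fate and a burst date).  No field dataset ships with
the package, so these generators produce statistically plausible stand-ins:
a sinusoidal southern-hemisphere temperature climate (coolest in July) with
Gaussian day-to-day noise, and ancestor populations sampled from
user-supplied category mixes.  Both are deterministic under a seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import FATES, POSITIONS, ValidationError

__all__ = ["WeatherSeries", "generate_weather", "generate_initial_tree", "AncestorSpec"]


@dataclass(frozen=True)
class AncestorSpec:
    position: str
    fate: str
    burst_date: dt.date


class WeatherSeries:
    """Contiguous daily mean-temperature calendar."""

    def __init__(self, dates: Sequence[dt.date], temperatures: Sequence[float]) -> None:
        if len(dates) != len(temperatures):
            raise ValidationError("dates and temperatures differ in length")
        if len(dates) == 0:
            raise ValidationError("weather series is empty")
        for prev, cur in zip(dates, dates[1:]):
            if (cur - prev).days != 1:
                raise ValidationError(f"weather dates not contiguous at {cur}")
        self._dates = list(dates)
        self._temps = {d: float(t) for d, t in zip(dates, temperatures)}

    @property
    def start(self) -> dt.date:
        return self._dates[0]

    @property
    def end(self) -> dt.date:
        return self._dates[-1]

    def temperature(self, date: dt.date) -> float:
        try:
            return self._temps[date]
        except KeyError:
            raise KeyError(f"no weather for {date} (series covers {self.start}..{self.end})")

    def covers(self, date: dt.date) -> bool:
        return self.start <= date <= self.end

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": [d.isoformat() for d in self._dates],
             "temperature_c": [self._temps[d] for d in self._dates]}
        )

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "WeatherSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        dates = [dt.date.fromisoformat(s) for s in df["date"]]
        return cls(dates, df["temperature_c"].tolist())


def generate_weather(
    start: dt.date,
    end: dt.date,
    mean_temp: float = 24.0,
    amplitude: float = 4.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> WeatherSeries:
    """Sinusoidal tropical climate, coolest mid-July, plus Gaussian noise.

    Defaults emulate a lowland Reunion-like regime (annual mean 24 degrees C,
    seasonal half-range 4 degrees C).
    """
    if start >= end:
        raise ValidationError("start must precede end")
    rng = np.random.default_rng(seed)
    dates = []
    d = start
    while d <= end:
        dates.append(d)
        d += dt.timedelta(days=1)
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    # minimum at day-of-year 196 (approx. 15 July)
    seasonal = mean_temp - amplitude * np.cos(2 * np.pi * (doy - 196) / 365.25)
    noise = rng.normal(0.0, noise_sd, size=len(dates)) if noise_sd > 0 else 0.0
    return WeatherSeries(dates, (seasonal + noise).tolist())


def _check_mix(name: str, mix: Mapping[str, float]) -> None:
    total = float(sum(mix.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{name} mix sums to {total}, not 1")
    if any(p < 0 for p in mix.values()):
        raise ValidationError(f"{name} mix has negative entries")


def generate_initial_tree(
    n_ancestors: int,
    position_mix: Mapping[str, float] | None = None,
    fate_mix: Mapping[str, float] | None = None,
    burst_month_mix: Mapping[int, float] | None = None,
    year: int = 2002,
    seed: int = 0,
) -> list[AncestorSpec]:
    """Sample an ancestor-GU population for the start of cycle 1.

    Defaults reflect a typical end-of-cycle canopy: mostly apical terminals,
    a majority of quiescent fates, and burst dates spread over the previous
    vegetative season (peaking in its first half).
    """
    position_mix = dict(position_mix or {"apical": 0.6, "lateral": 0.4})
    fate_mix = dict(fate_mix or {"quiescent": 0.6, "flowering": 0.25, "fruiting": 0.15})
    burst_month_mix = dict(
        burst_month_mix or {9: 0.25, 10: 0.25, 11: 0.2, 12: 0.15, 1: 0.1, 2: 0.05}
    )
    _check_mix("position", position_mix)
    _check_mix("fate", fate_mix)
    _check_mix("burst month", {str(k): v for k, v in burst_month_mix.items()})
    for p in position_mix:
        if p not in POSITIONS:
            raise ValidationError(f"unknown position {p!r}")
    for f in fate_mix:
        if f not in FATES:
            raise ValidationError(f"unknown fate {f!r}")

    rng = np.random.default_rng(seed)
    positions = rng.choice(list(position_mix), size=n_ancestors, p=list(position_mix.values()))
    fates = rng.choice(list(fate_mix), size=n_ancestors, p=list(fate_mix.values()))
    months = rng.choice(
        list(burst_month_mix), size=n_ancestors, p=list(burst_month_mix.values())
    )
    out = []
    for pos, fate, month in zip(positions, fates, months):
        month = int(month)
        # previous vegetative season: Aug-Dec belong to `year`, Jan-May to year+1
        y = year if month >= 8 else year + 1
        day = int(rng.integers(1, 28))
        out.append(AncestorSpec(str(pos), str(fate), dt.date(y, month, day)))
    return out


def ancestors_to_csv(ancestors: Sequence[AncestorSpec], path: str) -> None:
    pd.DataFrame(
        [
            {"position": a.position, "fate": a.fate, "burst_date": a.burst_date.isoformat()}
            for a in ancestors
        ]
    ).to_csv(path, index=False)


def ancestors_from_csv(path: str) -> list[AncestorSpec]:
    df = pd.read_csv(path)
    return [
        AncestorSpec(r["position"], r["fate"], dt.date.fromisoformat(r["burst_date"]))
        for _, r in df.iterrows()
    ]
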