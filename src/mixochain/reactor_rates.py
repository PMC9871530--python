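"""Production/consumption rates from semi-continuous reactor time series.

A semi-continuous reactor is fed by discrete exchange events: a fraction
``f`` of the broth is harvested and replaced with fresh medium.  Between
two consecutive broth samples the observed concentration change therefore
mixes biological conversion with dilution.  The rate estimator removes the
dilution part by first applying every intervening feed event to the start
concentration,

    rate = (C_end − C_start_adjusted) / Δt,

with the convention production positive / consumption negative.  Broth
samples are taken *before* feeding by default, so a feed event at a sample
time belongs to the interval it opens.

Gas uptake is inferred from the pressure decay of a well-mixed recirculated
gas volume (headspace + reservoir + lines) between reservoir
replenishments, using the ideal gas law; rates are normalised to the liquid
working volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FeedEvent",
    "BrothSample",
    "GasSample",
    "ReactorConfig",
    "RateRecord",
    "apply_feed_event",
    "interval_rates",
    "gas_phase_moles",
    "gas_consumption_rates",
    "cumulative_electron_profile",
    "R_GAS",
    "OD600_TO_G_DRY_WEIGHT",
]

#: Gas constant in L·bar·mol⁻¹·K⁻¹.
R_GAS = 0.08314

#: Dry biomass per OD600 unit, g L⁻¹.
OD600_TO_G_DRY_WEIGHT = 0.455


@dataclass(frozen=True)
class FeedEvent:
    """One harvest-and-feed exchange: fraction ``f`` of broth replaced."""

    time: float
    f: float
    feed_composition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"exchange fraction f={self.f} outside [0, 1]")


@dataclass(frozen=True)
class BrothSample:
    """Broth concentrations (mM) at one time point; optional OD600."""

    time: float
    concentrations: Mapping[str, float] = field(default_factory=dict)
    od600: float | None = None

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name} at t={self.time}")


@dataclass(frozen=True)
class GasSample:
    """Partial pressures (bar) of the recirculated gas at one time point."""

    time: float
    partial_pressures: Mapping[str, float] = field(default_factory=dict)
    is_post_replenishment: bool = False

    def __post_init__(self) -> None:
        for name, p in self.partial_pressures.items():
            if p < 0:
                raise ValueError(f"negative partial pressure for {name} at t={self.time}")


@dataclass(frozen=True)
class ReactorConfig:
    """Physical configuration of one reactor and its gas loop."""

    liquid_volume: float = 1.0          # L
    gas_system_volume: float = 5.0      # L, headspace + reservoir + lines
    temperature: float = 305.15         # K (32 °C)
    total_pressure: float = 1.0         # bar
    hrt: float = 14.0                   # days
    feed_interval: float = 1.0          # days

    def __post_init__(self) -> None:
        for name in ("liquid_volume", "gas_system_volume", "temperature",
                     "total_pressure", "hrt", "feed_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hrt < self.feed_interval:
            raise ValueError("hrt must be at least the feed interval")

    @property
    def exchange_fraction(self) -> float:
        """Per-event broth exchange fraction f = feed_interval / HRT."""
        return self.feed_interval / self.hrt


@dataclass(frozen=True)
class RateRecord:
    """Volumetric rate of one compound over one sampling interval.

    ``rate`` is in mmol L⁻¹ d⁻¹, production positive / consumption
    negative.
    """

    t_start: float
    t_end: float
    compound: str
    rate: float
    reactor_id: str | None = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError(
                f"t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def apply_feed_event(
    pre: Mapping[str, float], event: FeedEvent
) -> dict[str, float]:
    """Concentrations after one exchange event.

    C_post = C_pre·(1 − f) + C_feed·f per compound; compounds absent from
    the feed are treated as 0 mM in the fresh medium.
    """
    f = event.f
    names = set(pre) | set(event.feed_composition)
    return {
        n: pre.get(n, 0.0) * (1.0 - f) + event.feed_composition.get(n, 0.0) * f
        for n in names
    }


def interval_rates(
    samples: Sequence[BrothSample],
    events: Sequence[FeedEvent] = (),
    *,
    reactor_id: str | None = None,
    samples_are_pre_feed: bool = True,
) -> list[RateRecord]:
    """Dilution-corrected rates between consecutive broth samples.

    For each consecutive sample pair the start concentration is carried
    through every feed event inside the interval before differencing.
    With the default pre-feed sampling convention an event at the start
    time belongs to the interval ([t_start, t_end)); with post-feed
    sampling, to the preceding one ((t_start, t_end]).
    """
    samples = sorted(samples, key=lambda s: s.time)
    events = sorted(events, key=lambda e: e.time)
    if len(samples) < 2:
        return []
    if events:
        lo, hi = samples[0].time, samples[-1].time
        for e in events:
            inside = (lo <= e.time < hi) if samples_are_pre_feed else (lo < e.time <= hi)
            if not inside and not (lo <= e.time <= hi):
                raise ValueError(
                    f"feed event at t={e.time} outside sampled span [{lo}, {hi}]"
                )
    records: list[RateRecord] = []
    for a, b in zip(samples, samples[1:]):
        dt = b.time - a.time
        if dt <= 0:
            raise ValueError(f"non-increasing sample times at t={a.time}")
        adjusted = dict(a.concentrations)
        for e in events:
            inside = (
                (a.time <= e.time < b.time)
                if samples_are_pre_feed
                else (a.time < e.time <= b.time)
            )
            if inside:
                adjusted = apply_feed_event(adjusted, e)
        compounds = set(a.concentrations) | set(b.concentrations) | set(adjusted)
        for name in sorted(compounds):
            rate = (b.concentrations.get(name, 0.0) - adjusted.get(name, 0.0)) / dt
            records.append(
                RateRecord(a.time, b.time, name, rate, reactor_id=reactor_id)
            )
    return records


def gas_phase_moles(p: float, volume: float, temperature: float) -> float:
    """Ideal-gas moles (mmol) at partial pressure ``p`` (bar) in ``volume`` L."""
    if p < 0:
        raise ValueError("pressure must be non-negative")
    if volume <= 0 or temperature <= 0:
        raise ValueError("volume and temperature must be positive")
    return p * volume / (R_GAS * temperature) * 1000.0


def gas_consumption_rates(
    gas_samples: Sequence[GasSample],
    config: ReactorConfig,
    *,
    reactor_id: str | None = None,
) -> list[RateRecord]:
    """Per-gas rates (mmol per L liquid per day) between gas samples.

    The recirculated gas system is treated as one well-mixed volume.
    Replenishment of the reservoir is a step discontinuity: a sample
    flagged ``is_post_replenishment`` resets the baseline, and the
    pre/post pair straddling it contributes no rate.
    """
    ordered = sorted(
        gas_samples, key=lambda s: (s.time, s.is_post_replenishment)
    )
    records: list[RateRecord] = []
    for a, b in zip(ordered, ordered[1:]):
        if b.is_post_replenishment:
            continue  # baseline reset; the jump itself is not a rate
        dt = b.time - a.time
        if dt <= 0:
            raise ValueError(
                f"gas samples with identical time t={a.time} and no "
                "replenishment flag"
            )
        for gas in sorted(set(a.partial_pressures) | set(b.partial_pressures)):
            dn = gas_phase_moles(
                b.partial_pressures.get(gas, 0.0),
                config.gas_system_volume,
                config.temperature,
            ) - gas_phase_moles(
                a.partial_pressures.get(gas, 0.0),
                config.gas_system_volume,
                config.temperature,
            )
            records.append(
                RateRecord(
                    a.time,
                    b.time,
                    gas,
                    dn / (dt * config.liquid_volume),
                    reactor_id=reactor_id,
                )
            )
    return records


def cumulative_electron_profile(
    rates: Iterable[RateRecord],
    registry,
    *,
    gap_tolerance: float = 1e-9,
) -> pd.DataFrame:
    """Running electron totals per compound (e⁻-mmol L⁻¹ over time).

    Each interval contributes rate·Δt·γ.  The returned frame is indexed by
    interval-end time with one column per compound.  Gaps in interval
    coverage are carried forward with a warning.
    """
    by_compound: dict[str, list[RateRecord]] = {}
    for r in rates:
        by_compound.setdefault(r.compound, []).append(r)

    series: dict[str, pd.Series] = {}
    for compound, recs in by_compound.items():
        recs = sorted(recs, key=lambda r: r.t_start)
        gamma = registry[compound].gamma
        times, values = [recs[0].t_start], [0.0]
        total = 0.0
        prev_end = recs[0].t_start
        for r in recs:
            if r.t_start - prev_end > gap_tolerance:
                warnings.warn(
                    f"gap in rate coverage for {compound} between "
                    f"t={prev_end} and t={r.t_start}; carrying total forward",
                    stacklevel=2,
                )
            total += r.rate * r.duration * gamma
            times.append(r.t_end)
            values.append(total)
            prev_end = r.t_end
        series[compound] = pd.Series(values, index=pd.Index(times, name="time_d"))

    frame = pd.DataFrame(series).sort_index()
    return frame.ffill().fillna(0.0)
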