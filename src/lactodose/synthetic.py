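"""Synthetic environmental I-131 series.

Emulates the structure of post-accident monitoring data — a few short
high-concentration plume episodes over an exponentially decaying airborne
background, and a tap-water series that rises to a peak about a week after the
release and then declines quasi-exponentially with occasional missing sampling
days.  Magnitudes are order-of-magnitude plausible, deliberately NOT calibrated
to any measured monitoring record: every generated bundle is synthetic stand-in
data for exercising the pipeline.
"""

from __future__ import annotations

import dataclasses
import datetime

import numpy as np

from .constants import DEFAULT_ORIGIN
from .errors import ValidationError
from .scenarios import EnvSeries, SeriesBundle

__all__ = [
    "PlumeEvent",
    "PlumeSpec",
    "WaterSpec",
    "generate_air_series",
    "generate_water_series",
    "default_synthetic_bundle",
]


@dataclasses.dataclass(frozen=True)
class PlumeEvent:
    """One plume passage: onset, peak concentration, duration, gas/particulate split."""

    date: datetime.datetime
    peak_bq_m3: float
    duration_h: float
    gas_fraction: float

    def __post_init__(self) -> None:
        if self.peak_bq_m3 < 0:
            raise ValidationError("plume peak must be >= 0")
        if self.duration_h <= 0:
            raise ValidationError("plume duration must be > 0")
        if not (0 <= self.gas_fraction <= 1):
            raise ValidationError("gas fraction must be in [0, 1]")


def _default_events() -> tuple[PlumeEvent, ...]:
    # first plume arrival four days after the accident origin
    mk = lambda d, h, peak, dur, gf: PlumeEvent(
        datetime.datetime(2011, 3, d, h), peak, dur, gf
    )
    return (
        mk(15, 4, 150.0, 9.0, 0.6),
        mk(16, 2, 60.0, 6.0, 0.6),
        mk(21, 6, 40.0, 12.0, 0.65),
        mk(30, 12, 12.0, 9.0, 0.7),
    )


@dataclasses.dataclass(frozen=True)
class PlumeSpec:
    """Episodic-plume air series specification."""

    events: tuple[PlumeEvent, ...] = dataclasses.field(default_factory=_default_events)
    background_bq_m3: float = 2.0
    background_decay_per_d: float = 0.12
    background_gas_fraction: float = 0.6
    sampling_interval_h: float = 6.0
    window: tuple[datetime.date, datetime.date] = (
        datetime.date(2011, 3, 14),
        datetime.date(2011, 4, 25),
    )
    jitter_sigma: float = 0.3
    seed: int = 0
    origin: datetime.date = DEFAULT_ORIGIN

    def __post_init__(self) -> None:
        if self.background_bq_m3 < 0:
            raise ValidationError("background must be >= 0")
        if self.sampling_interval_h <= 0:
            raise ValidationError("sampling interval must be > 0")
        if not (0 <= self.background_gas_fraction <= 1):
            raise ValidationError("background gas fraction must be in [0, 1]")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter sigma must be >= 0")


@dataclasses.dataclass(frozen=True)
class WaterSpec:
    """Rise-then-decay tap-water series specification."""

    onset: datetime.date = datetime.date(2011, 3, 18)
    peak_bq_kg: float = 150.0
    rise_days: int = 3
    decline_half_time_d: float = 4.0
    missing_day_probability: float = 0.1
    end: datetime.date = datetime.date(2011, 4, 30)
    seed: int = 0
    origin: datetime.date = DEFAULT_ORIGIN

    def __post_init__(self) -> None:
        if self.peak_bq_kg < 0:
            raise ValidationError("peak must be >= 0")
        if self.decline_half_time_d <= 0:
            raise ValidationError("decline half-time must be > 0")
        if not (0 <= self.missing_day_probability < 1):
            raise ValidationError("missing-day probability must be in [0, 1)")
        if self.rise_days < 0:
            raise ValidationError("rise days must be >= 0")


def _days_since(origin: datetime.date, when: datetime.date | datetime.datetime) -> float:
    if isinstance(when, datetime.datetime):
        return (when - datetime.datetime.combine(origin, datetime.time())).total_seconds() / 86400.0
    return float((when - origin).days)


def generate_air_series(spec: PlumeSpec) -> tuple[EnvSeries, EnvSeries]:
    """Generate (gaseous, particulate) air series on a regular sampling grid."""
    rng = np.random.default_rng(spec.seed)
    peaks = np.array([e.peak_bq_m3 for e in spec.events], dtype=float)
    if spec.jitter_sigma > 0 and len(peaks):
        peaks = peaks * rng.lognormal(0.0, spec.jitter_sigma, size=len(peaks))

    t0 = _days_since(spec.origin, spec.window[0])
    t1 = _days_since(spec.origin, spec.window[1]) + 1.0
    dt = spec.sampling_interval_h / 24.0
    n = int(np.ceil((t1 - t0) / dt))
    starts = t0 + np.arange(n) * dt
    ends = np.minimum(starts + dt, t1)

    gas = np.zeros(n)
    part = np.zeros(n)
    # decaying background split by the background gas fraction
    bg = spec.background_bq_m3 * np.exp(-spec.background_decay_per_d * (starts - t0))
    gas += spec.background_gas_fraction * bg
    part += (1.0 - spec.background_gas_fraction) * bg
    # boxcar plumes, interval-overlap weighted
    for event, peak in zip(spec.events, peaks):
        es = _days_since(spec.origin, event.date)
        ee = es + event.duration_h / 24.0
        overlap = np.clip(np.minimum(ends, ee) - np.maximum(starts, es), 0.0, None)
        pulse = peak * overlap / (ends - starts)
        gas += event.gas_fraction * pulse
        part += (1.0 - event.gas_fraction) * pulse

    mk = lambda medium, conc: EnvSeries(medium, starts, conc, end=ends, origin=spec.origin)
    return mk("air_gaseous", gas), mk("air_particulate", part)


def generate_water_series(spec: WaterSpec) -> EnvSeries:
    """Generate a daily tap-water series, dropping days at the missing rate."""
    rng = np.random.default_rng(spec.seed)
    d0 = _days_since(spec.origin, spec.onset)
    d1 = _days_since(spec.origin, spec.end)
    days = np.arange(d0, d1 + 1.0)
    peak_day = d0 + spec.rise_days
    conc = np.where(
        days <= peak_day,
        spec.peak_bq_kg * np.where(
            spec.rise_days == 0, 1.0, (days - d0) / max(spec.rise_days, 1)
        ),
        spec.peak_bq_kg * 0.5 ** ((days - peak_day) / spec.decline_half_time_d),
    )
    keep = np.ones(len(days), dtype=bool)
    if spec.missing_day_probability > 0:
        keep = rng.random(len(days)) >= spec.missing_day_probability
        keep[0] = True  # keep the onset sample so "zero before sampling" stays anchored
    return EnvSeries("water", days[keep], conc[keep], origin=spec.origin)


def default_synthetic_bundle(seed: int = 0) -> SeriesBundle:
    """A complete synthetic bundle with the default plume and water structure."""
    gas, part = generate_air_series(PlumeSpec(seed=seed))
    water = generate_water_series(WaterSpec(seed=seed + 1))
    return SeriesBundle(air_gaseous=gas, air_particulate=part, water=water)
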