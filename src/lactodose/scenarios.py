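"""Exposure scenarios: environmental series + personal behaviour -> intake schedules.

The inhalation rate is C_air(t) x V where V is the daily effective breathing
volume; the ingestion rate is C_water(day) x D where D is the daily tap-water
consumption.  Air concentrations are held constant within each sampling period
and carried forward through gaps; tap-water concentrations are zero before the
first sample, linearly interpolated across missing days, and carried forward
after the last sample.

The effective breathing volume is

    V = F (B_S b_S,in + B_R b_R,in + B_LE b_LE,in) + B_LE b_LE,out

with activity-specific breathing rates B (m3/h), daily time budgets b (h/d)
and the indoor reduction factor F.  The default profile is a non-working
housewife's time budget with adult-female breathing rates; meal hours are
counted in the sleep-rate category.
"""

from __future__ import annotations

import dataclasses
import datetime
import math

import numpy as np
import pandas as pd

from .constants import DEFAULT_INDOOR_REDUCTION_FACTOR, DEFAULT_ORIGIN
from .errors import ConfigurationError, ValidationError
from .model_core import IntakeSchedule, Segment

__all__ = [
    "EnvSeries",
    "SeriesBundle",
    "BreathingProfile",
    "ScenarioConfig",
    "InfantProfile",
    "effective_breathing_volume",
    "infant_inhalation_volume",
    "air_series_to_rate",
    "water_series_to_rate",
    "build_schedule",
    "breathing_profile_preset",
]

_AIR_MEDIA = ("air_gaseous", "air_particulate")


class EnvSeries:
    """Environmental concentration series.

    Air media hold (start, end, concentration) sampling intervals in days since
    ``origin`` (Bq/m3); water holds (day, concentration) daily samples (Bq/kg),
    where NaN marks a sampled-but-missing day (to be interpolated downstream).
    """

    def __init__(
        self,
        medium: str,
        start: np.ndarray,
        conc: np.ndarray,
        end: np.ndarray | None = None,
        origin: datetime.date = DEFAULT_ORIGIN,
    ) -> None:
        if medium not in (*_AIR_MEDIA, "water"):
            raise ValidationError(f"unknown medium {medium!r}")
        start = np.asarray(start, dtype=float)
        conc = np.asarray(conc, dtype=float)
        if start.shape != conc.shape:
            raise ValidationError("start and conc must have equal length")
        order = np.argsort(start, kind="stable")
        start, conc = start[order], conc[order]
        if medium in _AIR_MEDIA:
            if end is None:
                raise ValidationError("air series requires interval ends")
            end = np.asarray(end, dtype=float)[order]
            if np.any(end <= start):
                raise ValidationError("air intervals must have end > start")
            if np.any(start[1:] < end[:-1] - 1e-9):
                raise ValidationError("air intervals must be non-overlapping")
            if np.any(np.isnan(conc)):
                keep = ~np.isnan(conc)
                start, end, conc = start[keep], end[keep], conc[keep]
        else:
            end = None
            if len(np.unique(start)) != len(start):
                raise ValidationError("duplicate water sampling days")
        with np.errstate(invalid="ignore"):
            if np.any(conc < 0):
                raise ValidationError("concentrations must be >= 0")
        self.medium = medium
        self.start = start
        self.end = end
        self.conc = conc
        self.origin = origin

    def __len__(self) -> int:
        return len(self.start)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnvSeries):
            return NotImplemented
        same_end = (
            (self.end is None and other.end is None)
            or (self.end is not None and other.end is not None
                and np.array_equal(self.end, other.end))
        )
        return (
            self.medium == other.medium
            and self.origin == other.origin
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.conc, other.conc, equal_nan=True)
            and same_end
        )

    def to_frame(self) -> pd.DataFrame:
        base = pd.Timestamp(self.origin)
        if self.medium in _AIR_MEDIA:
            return pd.DataFrame(
                {
                    "date_start": base + pd.to_timedelta(self.start, unit="D"),
                    "date_end": base + pd.to_timedelta(self.end, unit="D"),
                    "conc_Bq_m3": self.conc,
                }
            )
        return pd.DataFrame(
            {
                "date": base + pd.to_timedelta(self.start, unit="D"),
                "conc_Bq_kg": self.conc,
            }
        )


@dataclasses.dataclass(frozen=True)
class SeriesBundle:
    """The environmental series a residence's scenario is built from."""

    air_gaseous: EnvSeries | None = None
    air_particulate: EnvSeries | None = None
    water: EnvSeries | None = None


# ---------------------------------------------------------------------------
# breathing profiles

#: Housewife time budgets (h/d): meals counted at the sleep rate.
_T4_SLEEP_INDOOR = 7.62 + 1.45
_T4_REST_INDOOR = 0.433 + 2.08 + 0.100
_T4_LE_INDOOR = 1.07 + 4.67 + 4.37 + 0.0500
_T4_LE_OUTDOOR = 0.600 + 0.800 + 0.767


@dataclasses.dataclass(frozen=True)
class BreathingProfile:
    """Adult breathing rates (m3/h), time budgets (h/d) and indoor factor F."""

    rate_sleep: float = 0.32
    rate_rest: float = 0.39
    rate_light_exercise: float = 1.25
    sleep_indoor_h: float = _T4_SLEEP_INDOOR
    rest_indoor_h: float = _T4_REST_INDOOR
    light_exercise_indoor_h: float = _T4_LE_INDOOR
    light_exercise_outdoor_h: float = _T4_LE_OUTDOOR
    indoor_reduction_factor: float = DEFAULT_INDOOR_REDUCTION_FACTOR

    def __post_init__(self) -> None:
        vals = (
            self.rate_sleep, self.rate_rest, self.rate_light_exercise,
            self.sleep_indoor_h, self.rest_indoor_h,
            self.light_exercise_indoor_h, self.light_exercise_outdoor_h,
        )
        if any(v < 0 or not math.isfinite(v) for v in vals):
            raise ValidationError("rates and budgets must be finite and >= 0")
        if not (0 < self.indoor_reduction_factor <= 1):
            raise ValidationError("indoor reduction factor must be in (0, 1]")
        total = (
            self.sleep_indoor_h + self.rest_indoor_h
            + self.light_exercise_indoor_h + self.light_exercise_outdoor_h
        )
        if abs(total - 24.0) > 0.05:
            raise ValidationError(f"time budgets sum to {total} h, expected 24 +- 0.05")


def breathing_profile_preset(name: str) -> BreathingProfile:
    """Named behaviour presets: default, no_outdoor, max_outdoor."""
    if name == "default":
        return BreathingProfile()
    if name == "no_outdoor":
        # outdoor hours reassigned to rest-indoor
        return BreathingProfile(
            rest_indoor_h=_T4_REST_INDOOR + _T4_LE_OUTDOOR,
            light_exercise_outdoor_h=0.0,
        )
    if name == "max_outdoor":
        # all light-exercise hours spent outdoor
        return BreathingProfile(
            light_exercise_indoor_h=0.0,
            light_exercise_outdoor_h=_T4_LE_INDOOR + _T4_LE_OUTDOOR,
        )
    raise ConfigurationError(f"unknown breathing preset {name!r}")


def effective_breathing_volume(profile: BreathingProfile) -> float:
    """Daily effective breathing volume V (m3/day)."""
    indoor = (
        profile.rate_sleep * profile.sleep_indoor_h
        + profile.rate_rest * profile.rest_indoor_h
        + profile.rate_light_exercise * profile.light_exercise_indoor_h
    )
    outdoor = profile.rate_light_exercise * profile.light_exercise_outdoor_h
    return profile.indoor_reduction_factor * indoor + outdoor


@dataclasses.dataclass(frozen=True)
class InfantProfile:
    """3-month-old breast-fed infant: breathing, milk consumption and nursing window.

    The infant is assumed to stay indoors, so the indoor reduction factor
    applies to all breathing hours.
    """

    rate_asleep: float = 0.09
    rate_awake: float = 0.19
    asleep_h: float = 17.0
    awake_h: float = 7.0
    indoor_reduction_factor: float = DEFAULT_INDOOR_REDUCTION_FACTOR
    daily_milk_kg: float = 0.8
    nursing_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2011, 3, 14),
        datetime.date(2011, 4, 25),
    )

    def __post_init__(self) -> None:
        if abs(self.asleep_h + self.awake_h - 24.0) > 0.05:
            raise ValidationError("infant time budgets must sum to 24 h")
        if self.daily_milk_kg < 0:
            raise ValidationError("daily milk consumption must be >= 0")


def infant_inhalation_volume(profile: InfantProfile) -> float:
    """Infant daily effective breathing volume (m3/day), fully indoors."""
    return profile.indoor_reduction_factor * (
        profile.rate_asleep * profile.asleep_h + profile.rate_awake * profile.awake_h
    )


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    """Personal exposure configuration for one residence."""

    breathing_volume_m3_per_d: float = effective_breathing_volume(BreathingProfile())
    water_consumption_kg_per_d: float = 1.0
    origin: datetime.date = DEFAULT_ORIGIN
    end: datetime.date = datetime.date(2011, 4, 30)

    def __post_init__(self) -> None:
        if self.breathing_volume_m3_per_d <= 0:
            raise ValidationError("effective breathing volume must be > 0")
        if self.water_consumption_kg_per_d < 0:
            raise ValidationError("water consumption must be >= 0")
        if self.end <= self.origin:
            raise ValidationError("scenario end must be after origin")

    @property
    def horizon_days(self) -> float:
        return float((self.end - self.origin).days)


# ---------------------------------------------------------------------------
# series -> piecewise rates


def _air_route_segments(series: EnvSeries | None, v: float, until: float) -> list[Segment]:
    if series is None or len(series) == 0:
        return []
    segs: list[Segment] = []
    n = len(series)
    for i in range(n):
        s, e, c = series.start[i], series.end[i], series.conc[i]
        if s >= until:
            break
        e = min(e, until)
        if e > s and c > 0:
            segs.append(Segment(s, e, c * v))
        # carry the last period's concentration through the following gap
        nxt = series.start[i + 1] if i + 1 < n else until
        nxt = min(nxt, until)
        if nxt > series.end[i] and c > 0:
            segs.append(Segment(series.end[i], nxt, c * v))
    return segs


def air_series_to_rate(
    air_gas: EnvSeries | None,
    air_part: EnvSeries | None,
    breathing_volume_m3_per_d: float,
    until_day: float,
) -> dict[str, list[Segment]]:
    """Inhalation intake rates (Bq/day) per form: rate(t) = C_air(t) x V."""
    if breathing_volume_m3_per_d <= 0:
        raise ValidationError("breathing volume must be > 0")
    return {
        "vapour_inhalation": _air_route_segments(air_gas, breathing_volume_m3_per_d, until_day),
        "particulate_inhalation": _air_route_segments(air_part, breathing_volume_m3_per_d, until_day),
    }


def water_series_to_rate(
    water: EnvSeries | None,
    water_consumption_kg_per_d: float,
    until_day: float,
) -> list[Segment]:
    """Daily ingestion intake rate (Bq/day): rate(day) = C_water(day) x D.

    Zero before the first sample; interior missing days linearly interpolated
    from the adjacent observed days; trailing days carry the last value.
    """
    d = water_consumption_kg_per_d
    if d < 0:
        raise ValidationError("water consumption D must be >= 0")
    if d == 0 or water is None or len(water) == 0:
        return []
    obs = ~np.isnan(water.conc)
    if not obs.any():
        return []
    days_obs = water.start[obs]
    conc_obs = water.conc[obs]
    first = int(math.floor(days_obs[0]))
    last_day = int(math.ceil(until_day))
    segs: list[Segment] = []
    for day in range(first, last_day):
        if day < days_obs[0]:
            continue
        c = float(np.interp(day, days_obs, conc_obs))  # clamps after the last sample
        lo, hi = float(day), min(float(day + 1), until_day)
        if hi > lo and c > 0:
            segs.append(Segment(lo, hi, c * d))
    return segs


def build_schedule(
    config: ScenarioConfig,
    bundle: SeriesBundle,
) -> IntakeSchedule:
    """Merge the per-route rate functions into one intake schedule."""
    horizon = config.horizon_days
    for s in (bundle.air_gaseous, bundle.air_particulate, bundle.water):
        if s is not None and s.origin != config.origin:
            raise ConfigurationError(
                f"series origin {s.origin} differs from scenario origin {config.origin}"
            )
    if config.water_consumption_kg_per_d > 0 and bundle.water is None:
        raise ConfigurationError(
            "scenario requests tap-water ingestion (D > 0) but no water series is given"
        )
    routes = air_series_to_rate(
        bundle.air_gaseous, bundle.air_particulate,
        config.breathing_volume_m3_per_d, horizon,
    )
    routes["ingestion"] = water_series_to_rate(
        bundle.water, config.water_consumption_kg_per_d, horizon
    )
    return IntakeSchedule(routes, origin=config.origin)
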