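"""First-order compartmental kinetics with radioactive decay and scheduled intake.

The engine solves

    dy/dt = M y + b(t),      M = T - lambda I

where ``T`` holds first-order transfer coefficients between named compartments,
``lambda`` is the physical decay constant (applied identically in every
compartment, sinks included; progeny are untracked), and ``b(t)`` is a
piecewise-constant external input built from an :class:`IntakeSchedule` and a
per-route entry distribution.

Integration is classical fixed-step 4th-order Runge-Kutta.  For a linear system
with input held constant over a step, the four-stage update collapses exactly to

    y_{n+1} = P y_n + Q b,   P = sum_{j<=4} (hM)^j / j!,   Q = h sum_{j<=3} (hM)^j/(j+1)!

which is what is implemented (a test asserts equality with the explicit
stagewise form).  Intake discontinuities are snapped to the integration grid
with per-segment rate renormalisation so the administered integral is preserved
exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import (
    DEFAULT_ORIGIN,
    DEFAULT_OUTPUT_SPACING_DAYS,
    DEFAULT_STEP_DAYS,
    I131_HALF_LIFE_DAYS,
)
from .errors import (
    ConfigurationError,
    NumericalError,
    RangeError,
    StabilityError,
    ValidationError,
)

__all__ = [
    "CompartmentModel",
    "IntakeSchedule",
    "Segment",
    "SolverConfig",
    "ActivityTrajectory",
    "integrate",
    "total_system_activity",
]

_TIME_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class Segment:
    """One piecewise-constant intake segment: rate (Bq/day) over [start, end) days."""

    start: float
    end: float
    rate: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start) and math.isfinite(self.end)):
            raise ValidationError("segment bounds must be finite")
        if self.end <= self.start:
            raise ValidationError(f"segment end {self.end} must exceed start {self.start}")
        if not math.isfinite(self.rate) or self.rate < 0:
            raise ValidationError(f"segment rate must be finite and >= 0, got {self.rate}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def total(self) -> float:
        return self.rate * self.duration


class IntakeSchedule:
    """Piecewise-constant intake rates (Bq/day) per route on a common calendar origin."""

    def __init__(
        self,
        segments: Mapping[str, Sequence[Segment | tuple]],
        origin: datetime.date = DEFAULT_ORIGIN,
    ) -> None:
        self.origin = origin
        cleaned: dict[str, tuple[Segment, ...]] = {}
        for route, segs in segments.items():
            norm = tuple(s if isinstance(s, Segment) else Segment(*s) for s in segs)
            norm = tuple(sorted(norm, key=lambda s: s.start))
            for a, b in zip(norm, norm[1:]):
                if b.start < a.end - _TIME_TOL:
                    raise ValidationError(
                        f"route {route!r}: segments overlap at t={b.start}"
                    )
            cleaned[route] = norm
        self._segments = cleaned

    @property
    def routes(self) -> tuple[str, ...]:
        return tuple(self._segments)

    def segments(self, route: str) -> tuple[Segment, ...]:
        return self._segments.get(route, ())

    @property
    def end(self) -> float:
        """Last segment end over all routes (0 for an empty schedule)."""
        ends = [s.end for segs in self._segments.values() for s in segs]
        return max(ends) if ends else 0.0

    def total(self, route: str | None = None, t0: float = -math.inf, t1: float = math.inf) -> float:
        """Piecewise-constant integral of the rate over [t0, t1], in Bq."""
        routes = [route] if route is not None else list(self._segments)
        out = 0.0
        for r in routes:
            for s in self._segments.get(r, ()):
                lo, hi = max(s.start, t0), min(s.end, t1)
                if hi > lo:
                    out += s.rate * (hi - lo)
        return out

    @classmethod
    def acute(
        cls,
        route: str,
        amount_bq: float,
        at_day: float = 0.0,
        width_days: float = DEFAULT_STEP_DAYS,
        origin: datetime.date = DEFAULT_ORIGIN,
    ) -> "IntakeSchedule":
        """Acute intake approximated as a single short segment of exact total."""
        if amount_bq < 0:
            raise ValidationError("acute amount must be >= 0")
        if amount_bq == 0:
            return cls({route: []}, origin=origin)
        return cls(
            {route: [Segment(at_day, at_day + width_days, amount_bq / width_days)]},
            origin=origin,
        )

    def __add__(self, other: "IntakeSchedule") -> "IntakeSchedule":
        if other.origin != self.origin:
            raise ValidationError("cannot add schedules with different origins")
        merged: dict[str, list[Segment]] = {}
        for route in dict.fromkeys(self.routes + other.routes):
            segs = list(self.segments(route)) + list(other.segments(route))
            pts = sorted({p for s in segs for p in (s.start, s.end)})
            out: list[Segment] = []
            for lo, hi in zip(pts, pts[1:]):
                mid = 0.5 * (lo + hi)
                rate = sum(s.rate for s in segs if s.start <= mid < s.end)
                if rate > 0:
                    out.append(Segment(lo, hi, rate))
            merged[route] = out
        return IntakeSchedule(merged, origin=self.origin)

    # -- serialisation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"route": r, "start_day": s.start, "end_day": s.end, "rate_Bq_per_d": s.rate}
            for r in self.routes
            for s in self.segments(r)
        ]
        return pd.DataFrame(rows, columns=["route", "start_day", "end_day", "rate_Bq_per_d"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, origin: datetime.date = DEFAULT_ORIGIN) -> "IntakeSchedule":
        segs: dict[str, list[Segment]] = {}
        for row in frame.itertuples(index=False):
            segs.setdefault(str(row.route), []).append(
                Segment(float(row.start_day), float(row.end_day), float(row.rate_Bq_per_d))
            )
        return cls(segs, origin=origin)


@dataclasses.dataclass(frozen=True)
class SolverConfig:
    """Fixed-step solver settings (days)."""

    step: float = DEFAULT_STEP_DAYS
    output_spacing: float = DEFAULT_OUTPUT_SPACING_DAYS
    method: str = "rk4"

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError("step size must be > 0")
        ratio = self.output_spacing / self.step
        if abs(ratio - round(ratio)) > 1e-6 or round(ratio) < 1:
            raise ValidationError(
                "output grid spacing must be a positive integer multiple of the step size"
            )
        if self.method not in ("rk4", "euler"):
            raise ValidationError(f"unknown integration method {self.method!r}")

    @property
    def steps_per_output(self) -> int:
        return round(self.output_spacing / self.step)


class CompartmentModel:
    """Named compartments, first-order transfers (1/day) and a physical decay constant.

    Sinks are ordinary compartments whose only loss is radioactive decay; a
    transfer leaving a sink is rejected at construction.
    """

    def __init__(
        self,
        compartments: Sequence[str],
        transfers: Mapping[tuple[str, str], float],
        decay_constant: float,
        sinks: Iterable[str] = (),
    ) -> None:
        comps = tuple(compartments)
        if len(set(comps)) != len(comps):
            raise ValidationError("duplicate compartment names")
        index = {c: i for i, c in enumerate(comps)}
        sinks = frozenset(sinks)
        for s in sinks:
            if s not in index:
                raise ValidationError(f"sink {s!r} is not a compartment")
        if not (math.isfinite(decay_constant) and decay_constant > 0):
            raise ValidationError("decay_constant must be finite and > 0")
        seen: set[tuple[str, str]] = set()
        for (src, dst), k in transfers.items():
            if src not in index:
                raise ValidationError(f"transfer source {src!r} is not a compartment")
            if dst not in index:
                raise ValidationError(f"transfer destination {dst!r} is not a compartment")
            if src == dst:
                raise ValidationError(f"self-transfer {src!r} -> {dst!r} not allowed")
            if (src, dst) in seen:
                raise ValidationError(f"duplicate transfer {src!r} -> {dst!r}")
            seen.add((src, dst))
            if not (math.isfinite(k) and k >= 0):
                raise ValidationError(f"transfer rate {src}->{dst} must be finite and >= 0")
            if src in sinks and k > 0:
                raise ValidationError(f"transfer must not leave sink compartment {src!r}")
        self.compartments = comps
        self.index = index
        self.transfers = dict(transfers)
        self.decay_constant = float(decay_constant)
        self.sinks = sinks

    @property
    def n(self) -> int:
        return len(self.compartments)

    def matrix(self) -> np.ndarray:
        """System matrix M = T - decay*I with dy/dt = M y (+ inputs)."""
        m = np.zeros((self.n, self.n))
        for (src, dst), k in self.transfers.items():
            i, j = self.index[src], self.index[dst]
            m[j, i] += k
            m[i, i] -= k
        m -= self.decay_constant * np.eye(self.n)
        return m

    def max_total_outflow(self) -> float:
        """Largest per-compartment total outflow rate, decay included (1/day)."""
        out = {c: self.decay_constant for c in self.compartments}
        for (src, _dst), k in self.transfers.items():
            out[src] += k
        return max(out.values())

    # -- derived models ----------------------------------------------------

    def with_sink(self, compartment: str) -> "CompartmentModel":
        """Copy with all outflows from ``compartment`` removed and it marked a sink."""
        if compartment not in self.index:
            raise ConfigurationError(f"unknown compartment {compartment!r}")
        transfers = {
            pair: k for pair, k in self.transfers.items() if pair[0] != compartment
        }
        return CompartmentModel(
            self.compartments, transfers, self.decay_constant, self.sinks | {compartment}
        )

    def without_transfers(self, pairs: Iterable[tuple[str, str]]) -> "CompartmentModel":
        drop = set(pairs)
        transfers = {p: k for p, k in self.transfers.items() if p not in drop}
        return CompartmentModel(self.compartments, transfers, self.decay_constant, self.sinks)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "compartments": list(self.compartments),
            "half_life_days": math.log(2.0) / self.decay_constant,
            "sinks": sorted(self.sinks),
            "transfers": [
                [src, dst, float(k)] for (src, dst), k in sorted(self.transfers.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompartmentModel":
        transfers = {(src, dst): float(k) for src, dst, k in d["transfers"]}
        return cls(
            d["compartments"],
            transfers,
            math.log(2.0) / float(d.get("half_life_days", I131_HALF_LIFE_DAYS)),
            d.get("sinks", ()),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CompartmentModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class ActivityTrajectory:
    """Per-compartment activity (Bq) on a regular output grid.

    ``times`` are days since ``origin``; ``data`` is shaped (n_times, n_comp).
    ``administered`` is the cumulative activity delivered into the system up to
    each output time (entry-fraction scaled, no decay).
    """

    def __init__(
        self,
        times: np.ndarray,
        data: np.ndarray,
        compartments: Sequence[str],
        decay_constant: float,
        origin: datetime.date,
        administered: np.ndarray | None = None,
        sinks: frozenset[str] = frozenset(),
    ) -> None:
        self.times = np.asarray(times, dtype=float)
        self.data = np.asarray(data, dtype=float)
        self.compartments = tuple(compartments)
        self.index = {c: i for i, c in enumerate(self.compartments)}
        self.decay_constant = decay_constant
        self.origin = origin
        self.sinks = sinks
        self.administered = (
            np.zeros_like(self.times) if administered is None else np.asarray(administered)
        )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def _row(self, t: float) -> np.ndarray:
        lo, hi = self.span
        if t < lo - _TIME_TOL or t > hi + _TIME_TOL:
            raise RangeError(f"t={t} outside trajectory span [{lo}, {hi}]")
        spacing = self.times[1] - self.times[0] if len(self.times) > 1 else 1.0
        pos = (t - lo) / spacing
        i = int(round(pos))
        if 0 <= i < len(self.times) and abs(pos - i) < 1e-6:
            return self.data[i]
        j = min(max(int(math.floor(pos)), 0), len(self.times) - 2)
        w = pos - j
        return (1 - w) * self.data[j] + w * self.data[j + 1]

    def activity(self, compartment: str, t: float) -> float:
        if compartment not in self.index:
            raise ConfigurationError(f"unknown compartment {compartment!r}")
        return float(self._row(t)[self.index[compartment]])

    def total(self, t: float) -> float:
        """Total system activity (all compartments, sinks included) at time t."""
        return float(self._row(t).sum())

    def administered_to(self, t: float) -> float:
        lo, hi = self.span
        if t < lo - _TIME_TOL or t > hi + _TIME_TOL:
            raise RangeError(f"t={t} outside trajectory span [{lo}, {hi}]")
        return float(np.interp(t, self.times, self.administered))

    def daily_sink_delivery(self, compartment: str) -> pd.Series:
        """Activity delivered into a sink during each whole day, decay-referenced
        to the end of that day (i.e. the sink content that day's consumer would
        find if the sink were flushed at every day boundary)."""
        if compartment not in self.index:
            raise ConfigurationError(f"unknown compartment {compartment!r}")
        n_days = int(math.floor(self.span[1] + _TIME_TOL))
        carry = math.exp(-self.decay_constant)
        vals = []
        for d in range(n_days):
            v0 = self.activity(compartment, float(d))
            v1 = self.activity(compartment, float(d + 1))
            vals.append(max(v1 - v0 * carry, 0.0))
        idx = [self.origin + datetime.timedelta(days=d) for d in range(n_days)]
        return pd.Series(vals, index=idx, name=compartment)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: date (ISO timestamp), compartment, activity_Bq."""
        base = pd.Timestamp(self.origin)
        dates = base + pd.to_timedelta(self.times, unit="D")
        frames = []
        for c in self.compartments:
            frames.append(
                pd.DataFrame(
                    {
                        "date": dates,
                        "compartment": c,
                        "activity_Bq": self.data[:, self.index[c]],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def total_system_activity(trajectory: ActivityTrajectory, t: float) -> float:
    """Sum of all compartment activities (sinks included) at time ``t`` days."""
    return trajectory.total(t)


# ---------------------------------------------------------------------------
# integration


def _propagators(m: np.ndarray, h: float, method: str) -> tuple[np.ndarray, np.ndarray]:
    n = m.shape[0]
    eye = np.eye(n)
    a = h * m
    if method == "euler":
        return eye + a, h * eye
    a2 = a @ a
    a3 = a2 @ a
    a4 = a3 @ a
    p = eye + a + a2 / 2.0 + a3 / 6.0 + a4 / 24.0
    q = h * (eye + a / 2.0 + a2 / 6.0 + a3 / 24.0)
    return p, q


def _snap_segments(
    segs: Sequence[Segment], h: float, n_steps: int
) -> list[tuple[int, int, float]]:
    """Clip to [0, n_steps*h], snap boundaries to grid indices and renormalise
    rates so each segment's clipped integral is preserved exactly."""
    out: list[tuple[int, int, float]] = []
    for s in segs:
        lo = max(s.start, 0.0)
        hi = min(s.end, n_steps * h)
        if hi <= lo:
            continue
        i0 = int(round(lo / h))
        i1 = int(round(hi / h))
        if i1 <= i0:  # sub-step segment: deliver within a single step
            i0 = min(i0, n_steps - 1)
            i1 = i0 + 1
        total = s.rate * (hi - lo)
        out.append((i0, i1, total / ((i1 - i0) * h)))
    return out


def integrate(
    model: CompartmentModel,
    schedule: IntakeSchedule,
    entry_map: Mapping[str, Mapping[str, float]],
    duration: float,
    config: SolverConfig = SolverConfig(),
    initial: Mapping[str, float] | None = None,
) -> ActivityTrajectory:
    """Integrate the model under a schedule for ``duration`` days.

    ``entry_map`` gives, per route, the distribution of intake over compartments;
    fractions must be >= 0 and sum to <= 1 (the remainder never enters the system,
    e.g. exhaled air).  ``initial`` places activity in compartments at t = 0
    (an exact instantaneous intake, useful for impulse responses).
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    if initial:
        for comp, v in initial.items():
            if comp not in model.index:
                raise ConfigurationError(f"initial activity in unknown compartment {comp!r}")
            if v < 0:
                raise ValidationError("initial activity must be >= 0")
    for route, dist in entry_map.items():
        tot = 0.0
        for comp, frac in dist.items():
            if comp not in model.index:
                raise ConfigurationError(
                    f"entry_map for route {route!r} references unknown compartment {comp!r}"
                )
            if frac < 0:
                raise ConfigurationError(f"entry fraction {route}/{comp} must be >= 0")
            tot += frac
        if tot > 1.0 + 1e-9:
            raise ConfigurationError(
                f"entry fractions for route {route!r} sum to {tot:.6f} > 1"
            )
    for route in schedule.routes:
        if schedule.segments(route) and route not in entry_map:
            raise ConfigurationError(f"no entry distribution for route {route!r}")

    h = config.step
    limit = 1.0 / model.max_total_outflow()
    if h > limit:
        raise StabilityError(
            f"step size {h} day exceeds stability bound 1/max-outflow = {limit:.6g} day; "
            "reduce the step or the fastest transfer rate"
        )

    n_steps = max(int(round(duration / h)), 1)
    k = config.steps_per_output
    # pad so the run ends on an output boundary
    if n_steps % k:
        n_steps += k - n_steps % k
    n_out = n_steps // k

    routes = [r for r in schedule.routes if schedule.segments(r)]
    n_routes = len(routes)
    rate_steps = np.zeros((n_steps, max(n_routes, 1)))
    entry_cols = np.zeros((model.n, max(n_routes, 1)))
    entry_sum = np.zeros(max(n_routes, 1))
    for j, route in enumerate(routes):
        for i0, i1, rate in _snap_segments(schedule.segments(route), h, n_steps):
            rate_steps[i0:i1, j] += rate
        for comp, frac in entry_map[route].items():
            entry_cols[model.index[comp], j] = frac
        entry_sum[j] = sum(entry_map[route].values())

    m = model.matrix()
    p1, q1 = _propagators(m, h, config.method)
    pk = np.eye(model.n)
    sk = np.zeros((model.n, model.n))
    for _ in range(k):
        sk += pk
        pk = p1 @ pk

    y = np.zeros(model.n)
    init_total = 0.0
    if initial:
        for comp, v in initial.items():
            y[model.index[comp]] += v
            init_total += v
    out = np.zeros((n_out + 1, model.n))
    out[0] = y

    if n_routes:
        changed = np.nonzero(np.any(np.diff(rate_steps, axis=0) != 0.0, axis=1))[0] + 1
        bounds = [0, *changed.tolist(), n_steps]
    else:
        bounds = [0, n_steps]

    for a, b_end in zip(bounds, bounds[1:]):
        b_vec = entry_cols @ rate_steps[a] if n_routes else np.zeros(model.n)
        c1 = q1 @ b_vec
        ck = sk @ c1
        i = a
        while i < b_end and i % k:
            y = p1 @ y + c1
            i += 1
            if i % k == 0:
                out[i // k] = y
        while b_end - i >= k:
            y = pk @ y + ck
            i += k
            out[i // k] = y
        while i < b_end:
            y = p1 @ y + c1
            i += 1
            if i % k == 0:
                out[i // k] = y

    floor = out.min()
    if floor < -1e-9 * max(out.max(), 1.0):
        raise NumericalError(
            f"integration produced negative activity ({floor:.3g}); reduce the step size"
        )
    np.maximum(out, 0.0, out=out)

    times = np.arange(n_out + 1) * (k * h)
    cum = np.vstack([np.zeros((1, rate_steps.shape[1])), np.cumsum(rate_steps, axis=0) * h])
    administered = cum[::k][: n_out + 1] @ entry_sum + init_total
    return ActivityTrajectory(
        times,
        out,
        model.compartments,
        model.decay_constant,
        schedule.origin,
        administered=administered,
        sinks=model.sinks,
    )
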