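"""CSV/JSON readers and writers shared by all pipeline stages.

CSV dialects
------------
air:      date_start, date_end, conc_gaseous_Bq_m3, conc_particulate_Bq_m3
water:    date, conc_Bq_kg
schedule: route, start_day, end_day, rate_Bq_per_d

Dates are ISO-8601 (air bounds may carry a time of day).  Empty concentration
cells are missing values, never zeros.  Writers prepend ``#``-prefixed metadata
lines (package version, registry version, config hash, seed) so every output
is traceable; readers skip them.
"""

from __future__ import annotations

import csv
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import DEFAULT_ORIGIN
from .errors import ParseError, ValidationError
from .model_core import ActivityTrajectory, IntakeSchedule
from .scenarios import EnvSeries

__all__ = [
    "read_env_csv",
    "write_env_csv",
    "read_schedule_csv",
    "write_schedule_csv",
    "write_trajectory_csv",
    "write_milk_csv",
    "write_report_json",
    "config_hash",
    "metadata_lines",
]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata_lines(**extra) -> list[str]:
    from .registry import default_registry

    meta = {"lactodose": __version__, "registry": default_registry().version}
    meta.update(extra)
    return [f"# {k}={v}" for k, v in meta.items()]


def _write_with_header(path, frame: pd.DataFrame, **extra) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in metadata_lines(**extra):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def _parse_dt(value: str, line_no: int, field: str) -> pd.Timestamp:
    try:
        ts = pd.Timestamp(value)
        if pd.isna(ts):
            raise ValueError
        return ts
    except ValueError:
        raise ParseError(f"line {line_no}: malformed date in {field!r}: {value!r}") from None


def _parse_conc(value: str, line_no: int, field: str) -> float:
    if value is None or value.strip() == "":
        return float("nan")
    try:
        x = float(value)
    except ValueError:
        raise ParseError(f"line {line_no}: malformed number in {field!r}: {value!r}") from None
    if x < 0:
        raise ParseError(f"line {line_no}: negative concentration in {field!r}: {x}")
    return x


def _read_rows(path) -> tuple[list[str], list[tuple[int, dict]]]:
    with open(path, newline="") as fh:
        rows: list[tuple[int, list[str]]] = []
        for i, raw in enumerate(csv.reader(fh), start=1):
            if not raw or (raw[0].strip().startswith("#")):
                continue
            rows.append((i, raw))
    if not rows:
        raise ParseError("file has no data rows")
    header = [h.strip() for h in rows[0][1]]
    out = []
    for line_no, raw in rows[1:]:
        if len(raw) < len(header):
            raw = raw + [""] * (len(header) - len(raw))
        out.append((line_no, dict(zip(header, raw))))
    return header, out


def read_env_csv(
    path,
    medium: str,
    origin: datetime.date = DEFAULT_ORIGIN,
) -> EnvSeries:
    """Read one environmental series from an air or water CSV file."""
    header, rows = _read_rows(path)
    base = pd.Timestamp(origin)
    try:
        if medium in ("air_gaseous", "air_particulate"):
            col = "conc_gaseous_Bq_m3" if medium == "air_gaseous" else "conc_particulate_Bq_m3"
            for need in ("date_start", "date_end", col):
                if need not in header:
                    raise ParseError(f"air file missing column {need!r}")
            start, end, conc = [], [], []
            for line_no, row in rows:
                s = _parse_dt(row["date_start"], line_no, "date_start")
                e = _parse_dt(row["date_end"], line_no, "date_end")
                start.append((s - base) / pd.Timedelta(days=1))
                end.append((e - base) / pd.Timedelta(days=1))
                conc.append(_parse_conc(row.get(col, ""), line_no, col))
            return EnvSeries(medium, np.array(start), np.array(conc),
                             end=np.array(end), origin=origin)
        if medium == "water":
            for need in ("date", "conc_Bq_kg"):
                if need not in header:
                    raise ParseError(f"water file missing column {need!r}")
            day, conc = [], []
            for line_no, row in rows:
                d = _parse_dt(row["date"], line_no, "date")
                day.append((d - base) / pd.Timedelta(days=1))
                conc.append(_parse_conc(row.get("conc_Bq_kg", ""), line_no, "conc_Bq_kg"))
            return EnvSeries("water", np.array(day), np.array(conc), origin=origin)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc
    raise ParseError(f"unknown medium {medium!r}")


def write_env_csv(
    path,
    gaseous: EnvSeries | None = None,
    particulate: EnvSeries | None = None,
    water: EnvSeries | None = None,
    **extra,
) -> None:
    """Write an air CSV (gaseous and/or particulate) or a water CSV."""
    if water is not None:
        frame = water.to_frame().rename(columns={"conc_Bq_kg": "conc_Bq_kg"})
        frame["date"] = frame["date"].dt.strftime("%Y-%m-%d")
        _write_with_header(path, frame, **extra)
        return
    ref = gaseous if gaseous is not None else particulate
    if ref is None:
        raise ValidationError("nothing to write")
    frame = pd.DataFrame(
        {
            "date_start": pd.Timestamp(ref.origin) + pd.to_timedelta(ref.start, unit="D"),
            "date_end": pd.Timestamp(ref.origin) + pd.to_timedelta(ref.end, unit="D"),
        }
    )
    frame["date_start"] = frame["date_start"].dt.strftime("%Y-%m-%dT%H:%M")
    frame["date_end"] = frame["date_end"].dt.strftime("%Y-%m-%dT%H:%M")
    frame["conc_gaseous_Bq_m3"] = gaseous.conc if gaseous is not None else np.nan
    frame["conc_particulate_Bq_m3"] = (
        particulate.conc if particulate is not None else np.nan
    )
    _write_with_header(path, frame, **extra)


def write_schedule_csv(path, schedule: IntakeSchedule, **extra) -> None:
    frame = schedule.to_frame()
    _write_with_header(path, frame, origin=schedule.origin.isoformat(), **extra)


def read_schedule_csv(path, origin: datetime.date | None = None) -> IntakeSchedule:
    found_origin = origin
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "origin=" in line and origin is None:
                found_origin = datetime.date.fromisoformat(
                    line.split("origin=", 1)[1].strip()
                )
    frame = pd.read_csv(path, comment="#")
    try:
        return IntakeSchedule.from_frame(frame, origin=found_origin or DEFAULT_ORIGIN)
    except (ValidationError, KeyError, AttributeError) as exc:
        raise ParseError(f"bad schedule file: {exc}") from exc


def write_trajectory_csv(path, trajectory: ActivityTrajectory, **extra) -> None:
    frame = trajectory.to_frame()
    frame["date"] = frame["date"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    _write_with_header(path, frame, origin=trajectory.origin.isoformat(), **extra)


def write_milk_csv(path, milk: pd.Series, **extra) -> None:
    frame = pd.DataFrame(
        {"date": [d.isoformat() for d in milk.index], "milk_Bq_per_kg": milk.values}
    )
    _write_with_header(path, frame, **extra)


def write_report_json(path, report: dict, **extra) -> None:
    from .registry import default_registry

    payload = {
        "meta": {
            "lactodose": __version__,
            "registry": default_registry().version,
            **extra,
        },
        **report,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
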