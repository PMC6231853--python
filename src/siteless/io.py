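"""File formats: JSON-lines participant records, IMU trace CSV, TOML config.

Records are serialized one participant per line so that validation
errors can be reported with a line number and large cohorts can be
streamed.  Traces use the header ``t,gx,gy,gz,ax,ay,az`` in SI units
(seconds, rad/s, m/s^2).  Angles in serialized outputs are degrees with
three decimals.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .imu import IMUTrace, RomSettings, TraceFormatError
from .records import FunnelCounts, ParticipantRecord
from .simulate import CohortConfig

TRACE_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az"]


class RecordValidationError(ValueError):
    """A JSON-lines record failed schema validation; carries the line number."""

    def __init__(self, line_number: int, message: str) -> None:
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def read_records(path: str | Path) -> list[ParticipantRecord]:
    """Read and validate a JSON-lines participant file; blank lines are
    skipped; the first invalid line raises with its line number and the
    offending field."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(ParticipantRecord.model_validate_json(line))
            except ValidationError as exc:
                first = exc.errors()[0]
                loc = ".".join(str(x) for x in first["loc"]) or "record"
                raise RecordValidationError(
                    lineno, f"{loc}: {first['msg']}") from exc
            except json.JSONDecodeError as exc:
                raise RecordValidationError(lineno, f"invalid JSON: {exc}") from exc
    return records


def write_records(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.model_dump_json(exclude_none=True))
            fh.write("\n")


def read_trace_csv(path: str | Path, nominal_rate: float | None = None) -> IMUTrace:
    """Parse an IMU trace CSV with columns ``t,gx,gy,gz,ax,ay,az``.

    The nominal rate defaults to the inverse median sampling interval.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    bad = df[TRACE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        row = int(bad.isna().any(axis=1).idxmax())
        raise TraceFormatError(f"{path}: non-numeric value at data line {row + 2}")
    t = bad["t"].to_numpy(dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        k = int(np.argmax(np.diff(t) <= 0))
        raise TraceFormatError(
            f"{path}: timestamps not strictly increasing at data line {k + 3}")
    if nominal_rate is None:
        if t.size < 2:
            raise TraceFormatError(f"{path}: need at least 2 samples")
        nominal_rate = 1.0 / float(np.median(np.diff(t)))
    return IMUTrace(
        t=t,
        gyro=bad[["gx", "gy", "gz"]].to_numpy(dtype=float),
        accel=bad[["ax", "ay", "az"]].to_numpy(dtype=float),
        nominal_rate=nominal_rate,
    )


def write_trace_csv(trace: IMUTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([trace.t, trace.gyro, trace.accel]),
        columns=TRACE_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_funnel_json(path: str | Path) -> FunnelCounts:
    with open(path, encoding="utf-8") as fh:
        return FunnelCounts.model_validate(json.load(fh))


def write_funnel_json(counts: FunnelCounts, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(counts.model_dump(), fh, indent=2)
        fh.write("\n")


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Load a simulation config from TOML (any subset of CohortConfig
    fields; the rest take their defaults)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return CohortConfig.model_validate(data)


def load_rom_settings(path: str | Path) -> RomSettings:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RomSettings(**data)
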