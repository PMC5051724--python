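"""Reading and writing raw acceleration CSVs, activity logs and epoch tables.

Two plain-text raw dialects are supported:

* ``timestamped`` — header ``t,x,y,z``; ``t`` in seconds since recording
  start, sampled on a uniform grid.
* ``headerless_with_meta`` — comment lines ``# fs_hz=<Hz>`` and optionally
  ``# start=<ISO-8601>`` followed by ``x,y,z`` rows (an ``x,y,z`` header
  line is tolerated).

All loaded signals are expressed in milligravity (mg); files recorded in
gravitational units are scaled by 1000 on load.  Activity logs carry
start/end either as seconds since recording start or as ISO-8601 clock
times resolved against a supplied recording start.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, ValidationError

__all__ = [
    "RawRecording",
    "ActivityEntry",
    "ActivityLog",
    "read_raw_csv",
    "write_raw_csv",
    "read_activity_log",
    "write_activity_log",
    "read_epoch_table",
    "write_epoch_table",
    "EPOCH_TABLE_COLUMNS",
]

#: tolerance (s) when checking the uniform sampling grid of timestamped files
TIME_GRID_TOL_S = 1e-6

SEDENTARY_IDS = tuple(range(1, 12))
UPRIGHT_IDS = tuple(range(12, 17))
VALID_ACTIVITY_IDS = SEDENTARY_IDS + UPRIGHT_IDS


@dataclass
class RawRecording:
    """A uniformly sampled tri-axial acceleration time series in mg.

    Attributes
    ----------
    xyz : (n, 3) float array of per-axis acceleration in milligravity.
    fs : sampling frequency in Hz.
    brand : device brand, ``"AG"`` (ActiGraph), ``"GA"`` (GENEActiv) or
        ``"OTHER"``.
    placement : wear site, ``"hip"``, ``"wrist"`` or ``"other"``.
    participant_id : opaque participant identifier.
    """

    xyz: np.ndarray
    fs: float
    brand: str = "OTHER"
    placement: str = "other"
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValidationError(f"xyz must be (n, 3); got shape {self.xyz.shape}")
        if self.xyz.shape[0] < 1:
            raise ValidationError("a recording needs at least one sample")
        if not np.all(np.isfinite(self.xyz)):
            raise ValidationError("acceleration samples must be finite")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.xyz.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds since recording start."""
        return np.arange(self.n_samples) / self.fs

    def magnitudes(self) -> np.ndarray:
        """Per-sample vector magnitude r_i = sqrt(x^2+y^2+z^2), in mg."""
        return np.linalg.norm(self.xyz, axis=1)

    def with_xyz(self, xyz: np.ndarray) -> "RawRecording":
        return replace(self, xyz=xyz)


@dataclass(frozen=True)
class ActivityEntry:
    activity_id: int
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ActivityLog:
    """Time-ordered, non-overlapping labelled activity windows.

    Activity ids 1-11 are the lying/sitting (sedentary) postures, 12-16 the
    upright activities (standing, washing pots, dusting, sweeping, walking).
    """

    entries: list[ActivityEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = -np.inf
        for e in self.entries:
            if e.activity_id not in VALID_ACTIVITY_IDS:
                raise ValidationError(
                    f"activity_id {e.activity_id} outside the protocol range 1-16"
                )
            if not e.start_s < e.end_s:
                raise ValidationError(
                    f"activity {e.activity_id} ({e.label!r}): start {e.start_s} "
                    f"is not before end {e.end_s}"
                )
            if e.start_s < prev_end:
                raise ValidationError(
                    f"activity {e.activity_id} ({e.label!r}) overlaps the "
                    "previous entry"
                )
            prev_end = e.end_s

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def _finite_float(text: str, *, line_no: int, path: str) -> float:
    try:
        v = float(text)
    except ValueError as exc:
        raise ParseError(f"{path}: line {line_no}: cannot parse {text!r}") from exc
    if not np.isfinite(v):
        raise ParseError(f"{path}: line {line_no}: non-finite value {text!r}")
    return v


def read_raw_csv(
    path: str | Path,
    dialect: str = "timestamped",
    units: str = "g",
    *,
    brand: str = "OTHER",
    placement: str = "other",
    participant_id: str = "",
) -> RawRecording:
    """Load a raw tri-axial CSV into a :class:`RawRecording` in mg.

    Parameters
    ----------
    dialect : ``"timestamped"`` (``t,x,y,z`` rows; fs inferred from the time
        grid, which must be strictly increasing with a constant step) or
        ``"headerless_with_meta"`` (``# fs_hz=...`` header then ``x,y,z``).
    units : units of the file's axis columns; ``"g"`` values are multiplied
        by 1000 on load so the recording is always in mg.
    """
    path = Path(path)
    if dialect not in ("timestamped", "headerless_with_meta"):
        raise ConfigError(f"unknown raw dialect {dialect!r}")
    if units not in ("g", "mg"):
        raise ConfigError(f"unknown units {units!r}")

    fs = None
    data_lines: list[str] = []
    line_nos: list[int] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    if key.strip() == "fs_hz":
                        fs = _finite_float(val.strip(), line_no=line_no, path=str(path))
                continue
            first = line.split(",")[0].strip().lower()
            if first in ("t", "x"):  # column header line
                continue
            data_lines.append(line)
            line_nos.append(line_no)

    if not data_lines:
        raise ParseError(f"{path}: no data rows")

    n_cols = 4 if dialect == "timestamped" else 3
    rows = np.empty((len(data_lines), n_cols))
    for i, (line, line_no) in enumerate(zip(data_lines, line_nos)):
        parts = line.split(",")
        if len(parts) != n_cols:
            raise ParseError(
                f"{path}: line {line_no}: expected {n_cols} fields, got {len(parts)}"
            )
        for j, part in enumerate(parts):
            rows[i, j] = _finite_float(part.strip(), line_no=line_no, path=str(path))

    if dialect == "timestamped":
        t = rows[:, 0]
        xyz = rows[:, 1:]
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0))
                raise ValidationError(
                    f"{path}: timestamps not strictly increasing at data row {bad + 2}"
                )
            step = np.median(dt)
            if np.any(np.abs(dt - step) > TIME_GRID_TOL_S):
                raise ValidationError(f"{path}: non-uniform sampling grid")
            fs = 1.0 / step
        elif fs is None:
            raise ConfigError(
                f"{path}: cannot infer fs from a single-row timestamped file"
            )
    else:
        xyz = rows
        if fs is None:
            raise ConfigError(
                f"{path}: headerless dialect requires a '# fs_hz=' header line"
            )

    if units == "g":
        xyz = xyz * 1000.0
    return RawRecording(
        xyz=xyz,
        fs=float(fs),
        brand=brand,
        placement=placement,
        participant_id=participant_id,
    )


def write_raw_csv(rec: RawRecording, path: str | Path, dialect: str = "timestamped") -> None:
    """Write a recording (mg) in one of the supported dialects."""
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "timestamped":
            fh.write("t,x,y,z\n")
            t = rec.t
            for i in range(rec.n_samples):
                fh.write(
                    f"{t[i]:.6f},{rec.xyz[i, 0]:.17g},"
                    f"{rec.xyz[i, 1]:.17g},{rec.xyz[i, 2]:.17g}\n"
                )
        elif dialect == "headerless_with_meta":
            fh.write(f"# fs_hz={rec.fs:.17g}\n")
            fh.write("x,y,z\n")
            for i in range(rec.n_samples):
                fh.write(
                    f"{rec.xyz[i, 0]:.17g},{rec.xyz[i, 1]:.17g},{rec.xyz[i, 2]:.17g}\n"
                )
        else:
            raise ConfigError(f"unknown raw dialect {dialect!r}")


def _parse_log_time(value, recording_start, *, path: str) -> float:
    """A log time is either seconds-since-start or an ISO-8601 clock time."""
    try:
        return float(value)
    except (TypeError, ValueError):
        pass
    ts = pd.to_datetime(value, errors="coerce")
    if pd.isna(ts):
        raise ParseError(f"{path}: cannot parse time {value!r}")
    if recording_start is None:
        raise ConfigError(
            f"{path}: ISO-8601 log times require recording_start to be supplied"
        )
    start = pd.to_datetime(recording_start)
    return float((ts - start).total_seconds())


def read_activity_log(path: str | Path, recording_start=None) -> ActivityLog:
    """Read ``activity_id,label,start,end`` rows into an :class:`ActivityLog`.

    Times may be seconds since recording start or ISO-8601 clock times; the
    latter are resolved against ``recording_start``.  An empty file yields an
    empty (valid) log; downstream stages reject it.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return ActivityLog(entries=[])
    df = pd.read_csv(_io.StringIO(text))
    required = {"activity_id", "label", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            ActivityEntry(
                activity_id=int(row["activity_id"]),
                label=str(row["label"]),
                start_s=_parse_log_time(row["start"], recording_start, path=str(path)),
                end_s=_parse_log_time(row["end"], recording_start, path=str(path)),
            )
        )
    return ActivityLog(entries=entries)


def write_activity_log(log: ActivityLog, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "activity_id": e.activity_id,
                "label": e.label,
                "start": e.start_s,
                "end": e.end_s,
            }
            for e in log
        ]
    ).to_csv(path, index=False)


EPOCH_TABLE_COLUMNS = [
    "epoch_start",
    "participant_id",
    "brand",
    "placement",
    "activity_id",
    "enmo_mg",
    "mad_mg",
]


def write_epoch_table(metrics: pd.DataFrame, path: str | Path) -> None:
    """Write an epoch-metric table; round-trips losslessly with its reader.

    Floats are written with 17 significant digits so re-reading reproduces
    the exact double-precision values.
    """
    if len(metrics) == 0:
        raise ValidationError("refusing to write an empty epoch table")
    missing = [c for c in EPOCH_TABLE_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValidationError(f"epoch table missing columns {missing}")
    metrics[EPOCH_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_epoch_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "brand": str, "placement": str},
        float_precision="round_trip",
    )
    missing = [c for c in EPOCH_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: epoch table missing columns {missing}")
    df["activity_id"] = df["activity_id"].astype("Int64")
    return df
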