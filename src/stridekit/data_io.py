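"""Core recording types and the package's plain-text file dialect.

All internal quantities are SI (seconds, metres, rad/s, m/s^2).  Axis
convention throughout the package: X mediolateral, Y anterior (walking
direction), Z vertical (up).  Unit conversion happens exclusively inside the
readers, driven by the ``name[unit]`` column headers.

The CSV dialect is deliberately minimal and diff-able: a few leading
``# key = value`` metadata lines, then one header row with ``name[unit]``
columns (``time[s]`` first), then the samples.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import FormatError, SamplingError

if TYPE_CHECKING:  # pragma: no cover
    from .agreement import AgreementReport
    from .imu_events import GaitEventSet
    from .spatial import StrideTable

SIDES = ("left", "right")
MARKERS = ("heel", "toe", "ankle")

#: Maximum allowed deviation of consecutive time steps from 1/fs (seconds).
TIME_JITTER_TOL = 1e-6

_COL_RE = re.compile(r"^\s*([A-Za-z_][\w]*)\s*\[(.+)\]\s*$")

# multiplicative conversion into the internal SI unit, per quantity class
_UNIT_FACTORS = {
    "time": {"s": 1.0, "ms": 1e-3},
    "gyro": {"rad/s": 1.0, "deg/s": np.pi / 180.0},
    "accel": {"m/s^2": 1.0, "m/s2": 1.0, "g": 9.81},
    "pos": {"m": 1.0, "mm": 1e-3, "cm": 1e-2},
}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ImuRecording:
    """Uniformly sampled per-foot IMU traces.

    ``gyro_sensor`` is angular velocity in the sensor frame (rad/s, x is the
    mediolateral/pitch axis by mounting convention); ``accel_earth`` is
    acceleration resolved in the earth frame (m/s^2).  ``gravity_removed``
    records whether the vertical channel still contains gravity; the vendor
    pipeline may export either "free" or total earth-frame acceleration, so
    the flag is explicit rather than guessed.
    """

    time: np.ndarray
    fs: float
    gyro_sensor: np.ndarray
    accel_earth: np.ndarray
    side: str
    gravity_removed: bool = True

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.gyro_sensor = np.atleast_2d(np.asarray(self.gyro_sensor, dtype=float))
        self.accel_earth = np.atleast_2d(np.asarray(self.accel_earth, dtype=float))
        if self.fs <= 0:
            raise SamplingError(f"fs must be positive, got {self.fs}")
        if self.side not in SIDES:
            raise FormatError(f"side must be one of {SIDES}, got {self.side!r}")
        n = len(self.time)
        if self.gyro_sensor.shape != (n, 3) or self.accel_earth.shape != (n, 3):
            raise FormatError(
                "gyro and accel must both be (n_samples, 3) and match time length"
            )
        _check_uniform(self.time, self.fs)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def gyro_ml(self) -> np.ndarray:
        """Mediolateral (pitch) angular velocity channel."""
        return self.gyro_sensor[:, 0]

    @property
    def accel_vertical(self) -> np.ndarray:
        return self.accel_earth[:, 2]


@dataclass
class MarkerRecording:
    """Optical heel/toe/ankle marker positions per side plus pelvis (metres).

    ``mode`` selects the downstream event-detection frame: global coordinates
    on the treadmill, pelvis-relative coordinates overground.
    """

    time: np.ndarray
    fs: float
    markers: dict  # markers[side][name] -> (n, 3) position array
    pelvis: np.ndarray
    mode: str = "treadmill"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pelvis = np.asarray(self.pelvis, dtype=float)
        if self.fs <= 0:
            raise SamplingError(f"fs must be positive, got {self.fs}")
        if self.mode not in ("treadmill", "overground"):
            raise FormatError(f"mode must be treadmill/overground, got {self.mode!r}")
        n = len(self.time)
        for side in SIDES:
            if side not in self.markers:
                raise FormatError(f"missing marker side {side!r}")
            for name in MARKERS:
                if name not in self.markers[side]:
                    raise FormatError(f"missing {name!r} marker for side {side!r}")
                arr = np.asarray(self.markers[side][name], dtype=float)
                if arr.shape != (n, 3):
                    raise FormatError(f"marker {name}_{side} must be (n, 3)")
                self.markers[side][name] = arr
        if self.pelvis.shape != (n, 3):
            raise FormatError("pelvis must be (n, 3)")
        _check_uniform(self.time, self.fs)

    def __len__(self) -> int:
        return len(self.time)

    def get(self, side: str, name: str) -> np.ndarray:
        return self.markers[side][name]


@dataclass
class TrialMeta:
    """Trial bookkeeping carried through to output files."""

    participant_id: str = ""
    condition: str = "regular"  # regular | irregular
    group: str = "healthy"  # healthy | stroke
    walking_mode: str = "treadmill"  # treadmill | overground
    belt_mode: str = "none"  # self_paced | fixed | none

    def __post_init__(self) -> None:
        allowed = {
            "condition": ("regular", "irregular"),
            "group": ("healthy", "stroke"),
            "walking_mode": ("treadmill", "overground"),
            "belt_mode": ("self_paced", "fixed", "none"),
        }
        for attr, values in allowed.items():
            if getattr(self, attr) not in values:
                raise FormatError(f"{attr} must be one of {values}")


# ---------------------------------------------------------------------------
# helpers


def _check_uniform(time: np.ndarray, fs: float, tol: float = TIME_JITTER_TOL) -> None:
    if len(time) < 2:
        return
    dt = np.diff(time)
    if np.any(np.abs(dt - 1.0 / fs) > tol):
        worst = float(np.max(np.abs(dt - 1.0 / fs)))
        raise SamplingError(
            f"timestamps deviate from a uniform 1/{fs} s grid by up to {worst:.3g} s"
        )


def _read_with_meta(path) -> tuple[dict, pd.DataFrame]:
    """Split leading ``# key = value`` lines from the CSV body."""
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line.lstrip("#").partition("=")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no CSV body found")
    df = pd.read_csv(StringIO("".join(body_lines)))
    return meta, df


def _parse_columns(df: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """Map bare column name -> (full column label, unit)."""
    out = {}
    for col in df.columns:
        m = _COL_RE.match(col)
        if not m:
            raise FormatError(f"column {col!r} is not in 'name[unit]' form")
        out[m.group(1)] = (col, m.group(2))
    return out


def _column(df, cols, name: str, kind: str) -> np.ndarray:
    if name not in cols:
        raise FormatError(f"required column {name!r} missing")
    label, unit = cols[name]
    factors = _UNIT_FACTORS[kind]
    if unit not in factors:
        raise FormatError(f"column {label!r}: unit {unit!r} not understood for {kind}")
    return df[label].to_numpy(dtype=float) * factors[unit]


def _bool_meta(meta: dict, key: str, default: bool) -> bool:
    raw = meta.get(key)
    if raw is None:
        return default
    return raw.strip().lower() in ("1", "true", "yes")


# ---------------------------------------------------------------------------
# IMU CSV


def read_imu_csv(path, dialect: dict | None = None) -> ImuRecording:
    """Read a per-foot IMU recording from the documented CSV dialect.

    Metadata lines: ``# side = left``, ``# fs = 100``,
    ``# gravity_removed = true``.  Unit conversion (deg/s -> rad/s,
    g -> m/s^2) is applied according to each column's ``[unit]`` suffix.
    """
    meta, df = _read_with_meta(path)
    cols = _parse_columns(df)
    time = _column(df, cols, "time", "time")
    gyro = np.column_stack(
        [_column(df, cols, f"gyro_{ax}", "gyro") for ax in "xyz"]
    )
    accel = np.column_stack(
        [_column(df, cols, f"accel_{ax}", "accel") for ax in "xyz"]
    )
    fs = float(meta.get("fs", 0)) or _infer_fs(time)
    return ImuRecording(
        time=time,
        fs=fs,
        gyro_sensor=gyro,
        accel_earth=accel,
        side=meta.get("side", "left"),
        gravity_removed=_bool_meta(meta, "gravity_removed", True),
    )


def _infer_fs(time: np.ndarray) -> float:
    if len(time) < 2:
        raise SamplingError("cannot infer fs from fewer than 2 samples")
    return 1.0 / float(np.median(np.diff(time)))


def write_imu_csv(rec: ImuRecording, path) -> None:
    cols = {"time[s]": rec.time}
    for i, ax in enumerate("xyz"):
        cols[f"gyro_{ax}[rad/s]"] = rec.gyro_sensor[:, i]
    for i, ax in enumerate("xyz"):
        cols[f"accel_{ax}[m/s^2]"] = rec.accel_earth[:, i]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# side = {rec.side}\n")
        fh.write(f"# fs = {rec.fs:g}\n")
        fh.write(f"# gravity_removed = {str(rec.gravity_removed).lower()}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# marker CSV


def _marker_cols(side: str, name: str):
    s = side[0]  # l / r
    return [f"{name}_{s}_{ax}" for ax in "xyz"]


def read_marker_csv(path, dialect: dict | None = None) -> MarkerRecording:
    """Read heel/toe/ankle/pelvis marker positions (metres after conversion)."""
    meta, df = _read_with_meta(path)
    cols = _parse_columns(df)
    time = _column(df, cols, "time", "time")
    markers: dict = {}
    for side in SIDES:
        markers[side] = {}
        for name in MARKERS:
            arr = np.column_stack(
                [_column(df, cols, c, "pos") for c in _marker_cols(side, name)]
            )
            markers[side][name] = arr
    pelvis = np.column_stack(
        [_column(df, cols, f"pelvis_{ax}", "pos") for ax in "xyz"]
    )
    fs = float(meta.get("fs", 0)) or _infer_fs(time)
    return MarkerRecording(
        time=time,
        fs=fs,
        markers=markers,
        pelvis=pelvis,
        mode=meta.get("mode", "treadmill"),
    )


def write_marker_csv(rec: MarkerRecording, path) -> None:
    cols = {"time[s]": rec.time}
    for side in SIDES:
        for name in MARKERS:
            arr = rec.get(side, name)
            for i, c in enumerate(_marker_cols(side, name)):
                cols[f"{c}[m]"] = arr[:, i]
    for i, ax in enumerate("xyz"):
        cols[f"pelvis_{ax}[m]"] = rec.pelvis[:, i]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# mode = {rec.mode}\n")
        fh.write(f"# fs = {rec.fs:g}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# result writers

EVENT_CSV_COLUMNS = ["side", "event_type", "sample_index", "time_s"]
STRIDE_CSV_COLUMNS = [
    "side",
    "ic_start_s",
    "ic_end_s",
    "stride_time_s",
    "stride_length_m",
    "stride_velocity_mps",
    "valid",
    "exclusion_reason",
]

REPORT_SCHEMA_VERSION = 1


def write_events_csv(events: "GaitEventSet | list", path, fs: float | None = None) -> None:
    """Write gait events in long form, one row per event, times to 4 decimals.

    Accepts a single :class:`~stridekit.imu_events.GaitEventSet` or a list of
    them (typically left + right).
    """
    from .imu_events import GaitEventSet  # local import to avoid cycle

    if isinstance(events, GaitEventSet):
        events = [events]
    rows = []
    for ev in events:
        f = fs if fs is not None else ev.fs
        for name, idx in (
            ("midswing", ev.midswing_idx),
            ("ic", ev.ic_idx),
            ("tc", ev.tc_idx),
        ):
            for i in np.atleast_1d(idx):
                rows.append((ev.side, name, int(i), round(i / f, 4)))
        for start, end in ev.footflat:
            rows.append((ev.side, "footflat_start", int(start), round(start / f, 4)))
            rows.append((ev.side, "footflat_end", int(end), round(end / f, 4)))
    df = pd.DataFrame(rows, columns=EVENT_CSV_COLUMNS)
    df.sort_values(["side", "sample_index", "event_type"], inplace=True, kind="stable")
    df.to_csv(path, index=False)


def write_stride_csv(table: "StrideTable | list", path) -> None:
    from .spatial import StrideTable

    if isinstance(table, StrideTable):
        tables = [table]
    else:
        tables = list(table)
    frames = [t.to_dataframe() for t in tables]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=STRIDE_CSV_COLUMNS
    )
    for c in ("ic_start_s", "ic_end_s", "stride_time_s"):
        if len(df):
            df[c] = df[c].round(4)
    df.to_csv(path, index=False, float_format="%.6f")


def write_report_json(report: "AgreementReport", path) -> None:
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **report.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_report_json(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise FormatError(
            f"unsupported report schema version {payload.get('schema_version')!r}"
        )
    return payload


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
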