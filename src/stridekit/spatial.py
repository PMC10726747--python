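"""Strapdown integration with drift compensation and stride parameters.

The foot's earth-frame acceleration is integrated to velocity with a
rectangle-rule recurrence (v(t) = a(t)*Ts + v(t-1), v before the first sample
zero).  Integration drift is removed in two stages anchored on the detected
foot-flat phases, during which the foot is stationary relative to the support
surface:

1. a shape-preserving piecewise-cubic (PCHIP) curve through one anchor per
   foot-flat interval (interval midpoint, interval-mean raw velocity) is
   subtracted — the slowly varying, sigmoid-like drift estimate;
2. zero-velocity updates then remove the remaining piecewise-constant
   residual, so velocity is exactly zero-mean over every foot-flat.

Velocity is integrated once more to position, and stride time / length /
velocity are computed between consecutive initial contacts.  On a treadmill
the zero-velocity updates implicitly express the result in the belt frame,
which is why stride lengths remain comparable to overground walking.

Note the first strides are unreliable until the first foot-flat anchors the
integrator; they are kept in the table but flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import ParameterError
from .imu_events import GaitEventSet

#: residual foot-flat speed regarded as "zero" after updates (m/s)
ZUPT_TOLERANCE = 1e-6


@dataclass
class VelocityTrace:
    """Velocity at each de-drifting stage, all shaped (n, 3)."""

    time: np.ndarray
    v_raw: np.ndarray
    v_dedrifted: np.ndarray
    v_final: np.ndarray


@dataclass
class PositionTrace:
    time: np.ndarray
    p: np.ndarray  # (n, 3), p[0] = 0


@dataclass
class StrideRecord:
    side: str
    ic_start: float  # s
    ic_end: float  # s
    stride_time: float  # s
    stride_length: float  # m
    stride_velocity: float  # m/s
    valid: bool = True
    exclusion_reason: str = ""


@dataclass
class StrideTable:
    """Per-stride records plus on-demand trial summaries."""

    records: list = field(default_factory=list)
    provenance: str = "imu"

    def __len__(self):
        return len(self.records)

    def valid_records(self) -> list:
        return [r for r in self.records if r.valid]

    def values(self, param: str, valid_only: bool = True) -> np.ndarray:
        recs = self.valid_records() if valid_only else self.records
        return np.array([getattr(r, param) for r in recs], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "side": r.side,
                    "ic_start_s": r.ic_start,
                    "ic_end_s": r.ic_end,
                    "stride_time_s": r.stride_time,
                    "stride_length_m": r.stride_length,
                    "stride_velocity_mps": r.stride_velocity,
                    "valid": r.valid,
                    "exclusion_reason": r.exclusion_reason,
                }
                for r in self.records
            ],
            columns=[
                "side",
                "ic_start_s",
                "ic_end_s",
                "stride_time_s",
                "stride_length_m",
                "stride_velocity_mps",
                "valid",
                "exclusion_reason",
            ],
        )

    def summary(self) -> dict:
        return summarize_trial(self)


# ---------------------------------------------------------------------------
# integration


def integrate_acceleration(accel_earth: np.ndarray, fs: float) -> np.ndarray:
    """Rectangle-rule velocity: cumulative sum of a*Ts per axis, with the
    integration constant (velocity before the first sample) set to zero."""
    a = np.asarray(accel_earth, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ParameterError("acceleration contains non-finite values")
    return np.cumsum(a, axis=0) / fs


def integrate_velocity(v_final: np.ndarray, fs: float, time=None) -> PositionTrace:
    """Rectangle-rule position with p(0) anchored at the origin."""
    v = np.asarray(v_final, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ParameterError("velocity contains non-finite values")
    p = np.cumsum(v, axis=0) / fs
    p = p - p[0]
    if time is None:
        time = np.arange(len(v)) / fs
    return PositionTrace(time=np.asarray(time, dtype=float), p=p)


# ---------------------------------------------------------------------------
# drift compensation


def estimate_drift_curve(v_raw: np.ndarray, footflat: list) -> np.ndarray:
    """Sigmoid-like drift estimate through the foot-flat anchors.

    One anchor per foot-flat interval: x = interval midpoint (fractional
    sample), y = mean raw velocity over the interval.  A monotone PCHIP
    interpolant through the anchors is evaluated at every sample; beyond the
    outermost anchors the end cubic pieces are extended, which reproduces a
    linear (constant-bias) drift exactly.
    """
    v = np.atleast_2d(np.asarray(v_raw, dtype=float))
    if v.shape[0] == 1:
        v = v.T
    if len(footflat) < 2:
        raise ParameterError(
            f"need >= 2 foot-flat intervals to estimate drift, got {len(footflat)}"
        )
    xs = np.array([(s + e - 1) / 2.0 for s, e in footflat])
    ys = np.stack([v[s:e].mean(axis=0) for s, e in footflat])
    interp = PchipInterpolator(xs, ys, axis=0, extrapolate=True)
    drift = interp(np.arange(v.shape[0]))
    return drift.reshape(np.asarray(v_raw).shape)


def apply_zupt(v_dedrifted: np.ndarray, footflat: list) -> np.ndarray:
    """Zero-velocity updates: per segment between consecutive foot-flat
    starts, subtract the mean de-drifted velocity over the preceding
    foot-flat interval.  Samples before the first foot flat carry the first
    interval's correction (provisional; strides there are excluded
    downstream)."""
    v = np.array(v_dedrifted, dtype=float, copy=True)
    if not footflat:
        return v
    n = len(v)
    starts = [s for s, _ in footflat]
    for k, (s, e) in enumerate(footflat):
        offset = v_dedrifted[s:e].mean(axis=0)
        seg_start = 0 if k == 0 else starts[k]
        seg_end = starts[k + 1] if k + 1 < len(footflat) else n
        v[seg_start:seg_end] -= offset
    return v


def reconstruct_velocity(
    accel_earth: np.ndarray,
    footflat: list,
    fs: float,
    dedrift: bool = True,
    zupt: bool = True,
    time=None,
) -> VelocityTrace:
    """Full velocity chain: raw integration, drift curve, zero-velocity
    updates.  ``dedrift=False``/``zupt=False`` disable stages (used as a
    negative control to demonstrate the drift compensation is doing work)."""
    v_raw = integrate_acceleration(accel_earth, fs)
    if dedrift:
        drift = estimate_drift_curve(v_raw, footflat)
        v_dd = v_raw - drift
    else:
        v_dd = v_raw.copy()
    v_final = apply_zupt(v_dd, footflat) if zupt else v_dd.copy()
    if time is None:
        time = np.arange(len(v_raw)) / fs
    return VelocityTrace(
        time=np.asarray(time, dtype=float),
        v_raw=v_raw,
        v_dedrifted=v_dd,
        v_final=v_final,
    )


# ---------------------------------------------------------------------------
# stride parameters


def compute_strides(
    position: PositionTrace,
    events: GaitEventSet,
    first_footflat_end: float | None = None,
) -> StrideTable:
    """One record per consecutive IC pair.

    stride time = IC_n - IC_{n-1}; stride length = horizontal-plane distance
    sqrt(dX^2 + dY^2) travelled by the foot between the two ICs; stride
    velocity = length / time.  Strides starting before the end of the first
    foot flat are flagged invalid (the integrator is not yet anchored).
    """
    fs = events.fs
    ics = events.ic_idx
    table = StrideTable(provenance="imu")
    if ics.size < 2:
        return table
    if first_footflat_end is None:
        first_footflat_end = events.footflat[0][1] / fs if events.footflat else 0.0
    for i0, i1 in zip(ics[:-1], ics[1:]):
        t0, t1 = i0 / fs, i1 / fs
        dt = t1 - t0
        dx = position.p[i1, 0] - position.p[i0, 0]
        dy = position.p[i1, 1] - position.p[i0, 1]
        length = float(np.hypot(dx, dy))
        valid = t0 >= first_footflat_end
        table.records.append(
            StrideRecord(
                side=events.side,
                ic_start=t0,
                ic_end=t1,
                stride_time=dt,
                stride_length=length,
                stride_velocity=length / dt,
                valid=valid,
                exclusion_reason="" if valid else "before_first_footflat",
            )
        )
    return table


def summarize_trial(table: StrideTable) -> dict:
    """Trial summary over valid strides: mean, median, IQR, sample SD and
    CoV (%) per stride parameter.  CoV = SD / mean * 100."""
    valid = table.valid_records()
    if len(valid) < 2:
        raise ParameterError(
            f"need >= 2 valid strides to summarise, got {len(valid)}"
        )
    out = {"n_strides": len(valid), "n_excluded": len(table) - len(valid)}
    for param in ("stride_time", "stride_length", "stride_velocity"):
        x = np.array([getattr(r, param) for r in valid], dtype=float)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        q25, q50, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
        if mean == 0:
            raise ParameterError(f"mean {param} is zero; CoV undefined")
        out[param] = {
            "mean": mean,
            "median": float(q50),
            "iqr": float(q75 - q25),
            "sd": sd,
            "cov_pct": sd / mean * 100.0,
        }
    return out
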