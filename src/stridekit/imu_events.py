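"""Gait-event detection from filtered foot-mounted IMU signals.

Per foot, the detection chain is:

1. resolve the mounting sign so that swing peaks of the mediolateral (pitch)
   angular velocity point upward;
2. mid-swing = prominent peaks of the mediolateral angular velocity
   (peak distance 0.7 s, prominence 1 rad/s);
3. initial contact (IC) = first positive-to-negative zero crossing of the
   mediolateral angular velocity after each mid-swing;
4. terminal contact (TC) = vertical-acceleration peak between consecutive
   mid-swings, disambiguated (when several peaks exist) by the largest
   angular velocity in the anti-clockwise direction;
5. foot flat of one foot = from the contralateral TC to the contralateral
   mid-swing.

Indices are 0-based samples on the recording grid; foot-flat intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .data_io import ImuRecording
from .errors import DetectionError, ParameterError, TrialRejectedError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakCriteria:
    """Mid-swing peak-picking thresholds."""

    min_distance: float = 0.7  # s between consecutive mid-swing peaks
    min_prominence: float = 1.0  # rad/s

    def __post_init__(self):
        if self.min_distance <= 0 or self.min_prominence <= 0:
            raise ParameterError("peak criteria must be strictly positive")


@dataclass
class GaitEventSet:
    """Ordered per-foot gait events on the sample grid.

    Within each complete gait cycle the order is
    ``TC_k < midswing_k < IC_k < TC_{k+1}``.  ``footflat`` holds half-open
    ``[start, end)`` index intervals (derived from contralateral events).
    ``sign_convention`` is the factor applied to the mediolateral gyro before
    any rule was evaluated.
    """

    side: str
    midswing_idx: np.ndarray
    ic_idx: np.ndarray
    tc_idx: np.ndarray
    footflat: list = field(default_factory=list)
    sign_convention: int = 1
    fs: float = 100.0
    n_invalid_cycles: int = 0

    def __post_init__(self):
        self.midswing_idx = np.asarray(self.midswing_idx, dtype=int)
        self.ic_idx = np.asarray(self.ic_idx, dtype=int)
        self.tc_idx = np.asarray(self.tc_idx, dtype=int)

    def times(self, which: str) -> np.ndarray:
        """Event times in seconds for 'midswing', 'ic' or 'tc'."""
        return getattr(self, f"{which}_idx") / self.fs

    @property
    def footflat_times(self) -> list:
        return [(s / self.fs, e / self.fs) for s, e in self.footflat]


def resolve_sign_convention(gyro_ml: np.ndarray) -> int:
    """Return the sign that makes the dominant swing peaks positive.

    The physical convention ("maximum in the clockwise direction" at
    mid-swing) depends on which way the sensor is mounted; comparing the
    largest positive excursion against the largest negative one recovers it.
    """
    gyro_ml = np.asarray(gyro_ml, dtype=float)
    if gyro_ml.size == 0 or np.all(gyro_ml == 0):
        raise DetectionError("cannot resolve sign convention of an all-zero trace")
    return 1 if float(np.max(gyro_ml)) >= float(-np.min(gyro_ml)) else -1


def detect_midswing(
    gyro_ml: np.ndarray, criteria: PeakCriteria, fs: float
) -> np.ndarray:
    """Mid-swing = prominent positive peaks of the (sign-resolved)
    mediolateral angular velocity."""
    distance = max(1, int(round(criteria.min_distance * fs)))
    idx, _ = find_peaks(
        np.asarray(gyro_ml, dtype=float),
        distance=distance,
        prominence=criteria.min_prominence,
    )
    if idx.size == 0:
        warnings.warn("no mid-swing peaks found", stacklevel=2)
    return idx


def detect_initial_contacts(
    gyro_ml: np.ndarray, midswing: np.ndarray
) -> np.ndarray:
    """First positive-to-negative zero crossing after each mid-swing.

    The reported index is the first sample on the negative side.  Cycles
    whose signal never crosses zero before the next mid-swing yield no IC.
    """
    g = np.asarray(gyro_ml, dtype=float)
    midswing = np.asarray(midswing, dtype=int)
    if midswing.size == 0:
        return np.array([], dtype=int)
    neg = g < 0
    prev_nonneg = np.concatenate(([False], g[:-1] >= 0))
    crossing = np.flatnonzero(neg & prev_nonneg)
    ics = []
    bounds = np.concatenate((midswing[1:], [len(g)]))
    for ms, nxt in zip(midswing, bounds):
        cand = crossing[(crossing > ms) & (crossing < nxt)]
        if cand.size:
            ics.append(int(cand[0]))
    return np.array(ics, dtype=int)


def detect_terminal_contacts(
    accel_vertical: np.ndarray,
    gyro_ml: np.ndarray,
    midswing: np.ndarray,
) -> np.ndarray:
    """Vertical-acceleration peak between consecutive mid-swings.

    All local maxima in the window are candidates (no prominence floor); if
    more than one exists, the peak at the instant with the largest
    anti-clockwise (most negative, after sign resolution) angular velocity is
    taken as TC and the others treated as artefacts.
    """
    az = np.asarray(accel_vertical, dtype=float)
    g = np.asarray(gyro_ml, dtype=float)
    midswing = np.asarray(midswing, dtype=int)
    tcs = []
    for lo, hi in zip(midswing[:-1], midswing[1:]):
        seg = az[lo:hi]
        peaks, _ = find_peaks(seg)
        if peaks.size == 0:
            continue  # cycle invalid; no TC emitted
        best = peaks[np.argmin(g[lo + peaks])]
        tcs.append(int(lo + best))
    return np.array(tcs, dtype=int)


def detect_foot_flat(
    events_ipsi: GaitEventSet, events_contra: GaitEventSet
) -> list:
    """Foot-flat intervals for the ipsilateral foot.

    Start = contralateral TC, end = contralateral mid-swing (heel-off), as a
    half-open ``[start, end)`` index interval.  Intervals that would overlap
    an ipsilateral swing phase (TC..IC) indicate broken left/right
    interleaving and are dropped with a warning.
    """
    intervals = []
    ms = events_contra.midswing_idx
    for tc in events_contra.tc_idx:
        after = ms[ms > tc]
        if after.size == 0:
            continue
        intervals.append((int(tc), int(after[0])))
    # validity: must not intersect an ipsilateral swing (tc..ic) span
    swings = []
    for tc in events_ipsi.tc_idx:
        ic_after = events_ipsi.ic_idx[events_ipsi.ic_idx > tc]
        if ic_after.size:
            swings.append((int(tc), int(ic_after[0])))
    kept = []
    for s, e in intervals:
        if any(s < sw_e and e > sw_s for sw_s, sw_e in swings):
            warnings.warn(
                f"dropping foot-flat interval [{s}, {e}) overlapping an "
                f"ipsilateral swing (interleaving violated)",
                stacklevel=2,
            )
            continue
        kept.append((s, e))
    kept.sort()
    return kept


def _detect_one_foot(
    gyro_ml: np.ndarray,
    accel_vertical: np.ndarray,
    criteria: PeakCriteria,
    fs: float,
    side: str,
) -> GaitEventSet:
    sign = resolve_sign_convention(gyro_ml)
    g = sign * gyro_ml
    ms = detect_midswing(g, criteria, fs)
    ic = detect_initial_contacts(g, ms)
    tc = detect_terminal_contacts(accel_vertical, g, ms)
    n_invalid = max(0, (len(ms) - 1) - len(tc)) + max(0, len(ms) - len(ic))
    return GaitEventSet(
        side=side,
        midswing_idx=ms,
        ic_idx=ic,
        tc_idx=tc,
        sign_convention=sign,
        fs=fs,
        n_invalid_cycles=n_invalid,
    )


def detect_events(
    imu_left: ImuRecording,
    imu_right: ImuRecording,
    criteria: PeakCriteria | None = None,
) -> tuple[GaitEventSet, GaitEventSet]:
    """Detect all gait events for both feet of one trial.

    Expects *preprocessed* recordings (filtered, gravity removed).  Raises
    :class:`TrialRejectedError` when fewer than 3 valid cycles remain on
    either foot.
    """
    criteria = criteria or PeakCriteria()
    if len(imu_left) != len(imu_right):
        raise ParameterError("left and right recordings differ in length")
    if abs(imu_left.fs - imu_right.fs) > 1e-9:
        raise ParameterError("left and right recordings differ in fs")
    fs = imu_left.fs
    try:
        left = _detect_one_foot(
            imu_left.gyro_ml, imu_left.accel_vertical, criteria, fs, "left"
        )
        right = _detect_one_foot(
            imu_right.gyro_ml, imu_right.accel_vertical, criteria, fs, "right"
        )
    except DetectionError as exc:
        raise TrialRejectedError(f"event detection failed: {exc}") from exc
    left.footflat = detect_foot_flat(left, right)
    right.footflat = detect_foot_flat(right, left)
    for ev in (left, right):
        n_valid = _count_valid_cycles(ev)
        if n_valid < 3:
            raise TrialRejectedError(
                f"{ev.side} foot has only {n_valid} valid gait cycles (< 3)"
            )
        _assert_ordering(ev)
    log.info(
        "events: left %d IC / %d TC, right %d IC / %d TC",
        len(left.ic_idx), len(left.tc_idx), len(right.ic_idx), len(right.tc_idx),
    )
    return left, right


def _count_valid_cycles(ev: GaitEventSet) -> int:
    """A valid cycle has TC < mid-swing < IC in order."""
    n = 0
    for ms in ev.midswing_idx:
        tc_before = ev.tc_idx[ev.tc_idx < ms]
        ic_after = ev.ic_idx[ev.ic_idx > ms]
        if tc_before.size and ic_after.size:
            n += 1
    return n


def _assert_ordering(ev: GaitEventSet) -> None:
    for name in ("midswing_idx", "ic_idx", "tc_idx"):
        idx = getattr(ev, name)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise DetectionError(f"{ev.side} {name} not strictly increasing")
    for (s, e), (s2, _) in zip(ev.footflat, ev.footflat[1:]):
        if e > s2:
            raise DetectionError("foot-flat intervals overlap")
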