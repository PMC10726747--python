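"""Optical-marker (OMCS) reference method.

Velocity-based gait-event detection in the style of Zeni, Richards &
Higginson: terminal contact (TC) is the instant the anterior-posterior (AP)
velocity of the toe marker crosses zero in the anterior direction; initial
contact (IC) is the instant the AP velocity of the heel marker crosses zero
in the posterior direction.  On a treadmill the global marker coordinates are
used; overground, marker positions are taken relative to the pelvis so the
crossings are defined in the body frame.

Reference spatiotemporal parameters: stride time between consecutive ICs;
stride length overground as the AP heel-position difference between
consecutive ICs, and on a treadmill that difference plus the belt velocity
(estimated from the contralateral stance-foot marker during mid-stance)
multiplied by stride time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import MarkerRecording
from .errors import ParameterError
from .preprocessing import MARKER_CUTOFF_HZ, FilterSpec, lowpass_butterworth
from .spatial import StrideRecord, StrideTable

AP_AXIS = 1  # Y, the walking-direction axis


@dataclass
class ReferenceEvents:
    """Per-side IC/TC sample indices from the marker-velocity method."""

    side: str
    ic_idx: np.ndarray
    tc_idx: np.ndarray
    mode: str
    fs: float = 100.0

    def __post_init__(self):
        self.ic_idx = np.asarray(self.ic_idx, dtype=int)
        self.tc_idx = np.asarray(self.tc_idx, dtype=int)

    def times(self, which: str) -> np.ndarray:
        return getattr(self, f"{which}_idx") / self.fs


def marker_velocity(
    position: np.ndarray,
    fs: float,
    frame: str = "global",
    pelvis: np.ndarray | None = None,
) -> np.ndarray:
    """Central-difference AP velocity of a marker trace.

    ``position`` may be an (n,) AP coordinate or an (n, 3) position array
    (the AP column is taken).  ``frame='pelvis_relative'`` subtracts the
    pelvis trace first (overground walking).
    """
    pos = np.asarray(position, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, AP_AXIS]
    if frame == "pelvis_relative":
        if pelvis is None:
            raise ParameterError("pelvis trace required for pelvis_relative frame")
        pel = np.asarray(pelvis, dtype=float)
        if pel.ndim == 2:
            pel = pel[:, AP_AXIS]
        pos = pos - pel
    elif frame != "global":
        raise ParameterError(f"unknown frame {frame!r}")
    return np.gradient(pos, 1.0 / fs)


def _downward_crossings(v: np.ndarray) -> np.ndarray:
    """Indices where v goes from > 0 to <= 0 (posterior-direction crossing).

    The reported index is the first sample at or below zero, so a crossing
    that lands exactly on a sample is dated to that sample.
    """
    return np.flatnonzero((v[:-1] > 0) & (v[1:] <= 0)) + 1


def _upward_crossings(v: np.ndarray) -> np.ndarray:
    """Indices where v goes from < 0 to >= 0 (anterior-direction crossing)."""
    return np.flatnonzero((v[:-1] < 0) & (v[1:] >= 0)) + 1


def detect_reference_events(
    markers: MarkerRecording,
    filter_spec: FilterSpec | None = None,
    anterior_sign: int = 1,
) -> dict:
    """Zeni-style IC/TC per side from heel/toe AP velocity zero crossings.

    Returns ``{'left': ReferenceEvents, 'right': ReferenceEvents}``.  IC/TC
    are paired into cycles enforcing alternation (each IC is preceded by a
    TC of the same side).  ``anterior_sign=-1`` declares that the subject
    walks toward negative Y (mirrored walking direction).
    """
    spec = filter_spec or FilterSpec(MARKER_CUTOFF_HZ)
    frame = "global" if markers.mode == "treadmill" else "pelvis_relative"
    pelvis = lowpass_butterworth(markers.pelvis[:, AP_AXIS], spec, markers.fs)
    out = {}
    for side in ("left", "right"):
        heel = lowpass_butterworth(markers.get(side, "heel")[:, AP_AXIS], spec, markers.fs)
        toe = lowpass_butterworth(markers.get(side, "toe")[:, AP_AXIS], spec, markers.fs)
        v_heel = anterior_sign * marker_velocity(heel, markers.fs, frame, pelvis)
        v_toe = anterior_sign * marker_velocity(toe, markers.fs, frame, pelvis)
        ic = _downward_crossings(v_heel)
        tc = _upward_crossings(v_toe)
        if ic.size == 0 or tc.size == 0:
            warnings.warn(f"no reference events on side {side!r}", stacklevel=2)
        ic, tc = _enforce_alternation(ic, tc)
        out[side] = ReferenceEvents(
            side=side, ic_idx=ic, tc_idx=tc, mode=markers.mode, fs=markers.fs
        )
    return out


def _enforce_alternation(ic: np.ndarray, tc: np.ndarray):
    """Keep IC/TC pairs in strict TC_k < IC_k < TC_{k+1} order.

    For each TC the first following IC before the next TC is kept; unmatched
    events are dropped.
    """
    keep_ic, keep_tc = [], []
    bounds = np.concatenate((tc[1:], [np.iinfo(np.int64).max]))
    for t, nxt in zip(tc, bounds):
        cand = ic[(ic > t) & (ic < nxt)]
        if cand.size:
            keep_tc.append(int(t))
            keep_ic.append(int(cand[0]))
    return np.array(keep_ic, dtype=int), np.array(keep_tc, dtype=int)


def swing_time(ic: float, prev_tc: float) -> float:
    """Swing duration IC_n - TC_{n-1} (seconds)."""
    st = ic - prev_tc
    if st <= 0:
        raise ParameterError(f"non-positive swing time {st}")
    return st


def belt_velocity(
    contra_pos_ap: np.ndarray,
    tc: float,
    swing: float,
    fs: float,
) -> float:
    """Belt velocity from the contralateral stance-foot marker.

    Average backward AP speed of the contralateral marker over the central
    half of the ipsilateral swing: position difference between TC + 0.1*swing
    and TC + 0.6*swing divided by the elapsed time (nominally 0.5*swing).
    Sample instants are resolved to the nearest sample (no sub-sample
    interpolation at 100 Hz); the elapsed time is taken between the samples
    actually used, which keeps the average unbiased on the sample grid.
    """
    pos = np.asarray(contra_pos_ap, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, AP_AXIS]
    i1 = int(round((tc + 0.1 * swing) * fs))
    i2 = int(round((tc + 0.6 * swing) * fs))
    if not (0 <= i1 < len(pos) and 0 <= i2 < len(pos)):
        raise ParameterError("belt-velocity window falls outside the recording")
    if i2 <= i1:
        raise ParameterError("belt-velocity window collapses at this fs")
    return float((pos[i1] - pos[i2]) / ((i2 - i1) / fs))


def reference_stride_length(
    markers: MarkerRecording,
    events: ReferenceEvents,
    contra_events: ReferenceEvents | None = None,
    belt_marker: str = "ankle",
) -> StrideTable:
    """Reference stride table from marker data (provenance "omcs").

    Overground: stride length = AP heel-position delta between consecutive
    ICs (global frame).  Treadmill: that delta plus belt velocity times
    stride time, with belt velocity estimated per cycle from the
    contralateral ``belt_marker`` (ankle by default).  When the belt
    velocity cannot be computed for a treadmill cycle the stride is flagged
    invalid.
    """
    fs = markers.fs
    heel_ap = markers.get(events.side, "heel")[:, AP_AXIS]
    contra_side = "right" if events.side == "left" else "left"
    contra_ap = markers.get(contra_side, belt_marker)[:, AP_AXIS]
    ic = events.ic_idx
    tc = events.tc_idx
    table = StrideTable(provenance="omcs")
    if ic.size < 2:
        return table
    for n in range(1, ic.size):
        t0, t1 = ic[n - 1] / fs, ic[n] / fs
        dt = t1 - t0
        dy = float(heel_ap[ic[n]] - heel_ap[ic[n - 1]])
        valid = True
        reason = ""
        if markers.mode == "treadmill":
            try:
                prev_tc = tc[tc < ic[n]]
                if prev_tc.size == 0:
                    raise ParameterError("no TC before IC")
                sw = swing_time(ic[n] / fs, prev_tc[-1] / fs)
                belt = belt_velocity(contra_ap, prev_tc[-1] / fs, sw, fs)
            except ParameterError:
                belt = 0.0
                valid = False
                reason = "belt_velocity_unavailable"
            length = dy + belt * dt
        else:
            length = dy
        table.records.append(
            StrideRecord(
                side=events.side,
                ic_start=t0,
                ic_end=t1,
                stride_time=dt,
                stride_length=length,
                stride_velocity=length / dt,
                valid=valid,
                exclusion_reason=reason,
            )
        )
    return table


def analyze_reference_trial(
    markers: MarkerRecording, belt_marker: str = "ankle"
) -> tuple[dict, dict]:
    """Run the full reference pipeline: events and stride tables per side."""
    events = detect_reference_events(markers)
    strides = {
        side: reference_stride_length(markers, ev, belt_marker=belt_marker)
        for side, ev in events.items()
    }
    return events, strides
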