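"""End-to-end orchestration of the IMU analysis chain.

Thin glue used by the CLI and the validation layer: filter, remove gravity,
detect events, reconstruct velocity/position with drift compensation, and
compute the stride table, per foot.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_io import ImuRecording
from .imu_events import GaitEventSet, PeakCriteria, detect_events
from .preprocessing import (
    ACCEL_CUTOFF_HZ,
    GYRO_CUTOFF_HZ,
    FilterSpec,
    lowpass_butterworth,
    remove_gravity,
)
from .spatial import (
    PositionTrace,
    StrideTable,
    VelocityTrace,
    compute_strides,
    integrate_velocity,
    reconstruct_velocity,
)


@dataclass
class FootResult:
    events: GaitEventSet
    velocity: VelocityTrace
    position: PositionTrace
    strides: StrideTable


@dataclass
class TrialResult:
    left: FootResult
    right: FootResult

    def events(self) -> dict:
        return {"left": self.left.events, "right": self.right.events}

    def strides(self) -> dict:
        return {"left": self.left.strides, "right": self.right.strides}


def preprocess_imu(
    rec: ImuRecording,
    gyro_filter: FilterSpec | None = None,
    accel_filter: FilterSpec | None = None,
) -> ImuRecording:
    """Filtered, gravity-free copy of a raw recording."""
    gspec = gyro_filter or FilterSpec(GYRO_CUTOFF_HZ)
    aspec = accel_filter or FilterSpec(ACCEL_CUTOFF_HZ)
    gyro = lowpass_butterworth(rec.gyro_sensor, gspec, rec.fs)
    accel = remove_gravity(rec.accel_earth, rec.gravity_removed)
    accel = lowpass_butterworth(accel, aspec, rec.fs)
    return ImuRecording(
        time=rec.time, fs=rec.fs, gyro_sensor=gyro, accel_earth=accel,
        side=rec.side, gravity_removed=True,
    )


def analyze_imu_trial(
    imu_left: ImuRecording,
    imu_right: ImuRecording,
    criteria: PeakCriteria | None = None,
    gyro_filter: FilterSpec | None = None,
    accel_filter: FilterSpec | None = None,
    dedrift: bool = True,
    zupt: bool = True,
) -> TrialResult:
    """Full IMU pipeline for one trial.

    ``dedrift=False`` / ``zupt=False`` disable the corresponding drift
    compensation stage (negative control; events are still detected on the
    conditioned signals).
    """
    left_pp = preprocess_imu(imu_left, gyro_filter, accel_filter)
    right_pp = preprocess_imu(imu_right, gyro_filter, accel_filter)
    ev_left, ev_right = detect_events(left_pp, right_pp, criteria)
    results = []
    for rec, ev in ((left_pp, ev_left), (right_pp, ev_right)):
        vel = reconstruct_velocity(
            rec.accel_earth, ev.footflat, rec.fs,
            dedrift=dedrift, zupt=zupt, time=rec.time,
        )
        pos = integrate_velocity(vel.v_final, rec.fs, time=rec.time)
        first_ff_end = ev.footflat[0][1] / rec.fs if ev.footflat else 0.0
        strides = compute_strides(pos, ev, first_ff_end)
        results.append(FootResult(events=ev, velocity=vel, position=pos,
                                  strides=strides))
    return TrialResult(left=results[0], right=results[1])
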