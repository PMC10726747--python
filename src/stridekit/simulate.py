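"""Seeded synthetic gait generator with exact ground truth.

The generator builds, per foot, an alternating sequence of phases: foot flat
(zero velocity relative to the support surface), a short push-off transition
straddling terminal contact, a smooth swing, and a short landing transition
after initial contact.  The anterior-posterior swing profile is a
minimum-jerk interpolant (zero velocity and acceleration at both ends,
single velocity hump, programmed displacement); the vertical profile is a
symmetric triple-bump acceleration with its first peak exactly at TC, so the
vertical-acceleration signature used by the IMU event rules coincides with
the true liftoff instant.  The pitch angular velocity has one dominant
positive lobe peaking at mid-swing, ending with a negative-going zero
crossing exactly at IC, preceded by a plantarflexion (negative) bump centred
on TC — the morphology the detection rules assume.

Marker trajectories are constructed so that the reference method's
zero-crossing events land on the true IC/TC by design: the heel keeps moving
briefly after contact and crosses the frame velocity (belt speed on a
treadmill, pelvis speed overground) exactly at IC, while the toe lifts early
during push-off and crosses it exactly at TC.  The pelvis is a
constant-velocity trace.

Treadmill trials hold the belt at constant speed (defaulting to the mean
progression speed); stepping-stone trials draw each stride length from a
discrete set of multipliers of the base length (80-120 % by default).
All randomness flows from one seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

from .data_io import ImuRecording, MarkerRecording, write_imu_csv, write_marker_csv
from .errors import ParameterError

# waveform geometry (seconds / rad/s); chosen once for plausible adult gait
VERT_BUMP_S = 0.08  # width of the vertical push-off / landing accel bumps
GYRO_PUSHOFF_S = 0.12  # width of the plantarflexion bump centred on TC
# the landing bump must end before the contralateral TC (~0.1 x stride time
# after IC with a 0.4 swing fraction), when this foot's flat phase begins
GYRO_LANDING_S = 0.08  # width of the post-IC negative bump
GYRO_SWING_PEAK = 3.5  # rad/s, dominant mid-swing lobe amplitude
GYRO_PUSHOFF_PEAK = 2.5  # rad/s
GYRO_LANDING_PEAK = 1.2  # rad/s

DEFAULT_LEVELS = (80.0, 90.0, 100.0, 110.0, 120.0)


@dataclass
class GaitSimulationParams:
    """Study-condition parameters of one simulated trial.

    Defaults reproduce regular treadmill walking of a healthy adult:
    stride time 1.05 s, stride length 1.32 m, 2 % stride-time variability,
    50 strides, 100 Hz sampling, noise-free sensors.
    """

    n_strides: int = 50
    stride_time_mean: float = 1.05  # s
    stride_time_cov: float = 2.0  # % of the mean
    base_stride_length: float = 1.32  # m
    length_pattern: str = "regular"  # regular | stepping_stones
    stepping_levels: tuple = DEFAULT_LEVELS  # % of base length
    mode: str = "treadmill"  # treadmill | overground
    belt_speed: float | None = None  # m/s; None -> mean progression speed
    swing_fraction: float = 0.4
    foot_clearance: float = 0.08  # m, peak foot height in swing
    fs: float = 100.0
    noise_accel: float = 0.0  # m/s^2 SD, per axis
    noise_gyro: float = 0.0  # rad/s SD, per axis
    accel_bias: float = 0.0  # m/s^2, constant, all axes
    accel_bias_drift: float = 0.0  # m/s^3, linear ramp, all axes
    seed: int = 0
    lead_in: float = 2.0  # s of quiet standing before the first push-off
    tail: float = 1.5  # s of quiet standing after the last landing

    def validate(self) -> None:
        if self.n_strides < 1:
            raise ParameterError("n_strides must be >= 1")
        for name in ("stride_time_mean", "base_stride_length", "fs",
                     "foot_clearance"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0.2 < self.swing_fraction < 0.6:
            raise ParameterError("swing_fraction must lie in (0.2, 0.6)")
        if self.length_pattern not in ("regular", "stepping_stones"):
            raise ParameterError(f"unknown length_pattern {self.length_pattern!r}")
        if self.mode not in ("treadmill", "overground"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if any(l <= 0 for l in self.stepping_levels):
            raise ParameterError("stepping levels must be positive")
        swing = self.swing_fraction * self.stride_time_mean
        stance = (1 - self.swing_fraction) * self.stride_time_mean
        if swing <= VERT_BUMP_S + 0.05 or stance <= GYRO_PUSHOFF_S + GYRO_LANDING_S:
            raise ParameterError("phase split infeasible for the waveform widths")


@dataclass
class GroundTruth:
    """Exact event times and stride parameters recorded from construction."""

    feet: dict  # side -> {tc_times, midswing_times, ic_times, footflat, strides}
    mode: str
    belt_speed: float
    fs: float

    def events(self, side: str, which: str) -> np.ndarray:
        key = {"tc": "tc_times", "ic": "ic_times", "midswing": "midswing_times"}[which]
        return np.asarray(self.feet[side][key], dtype=float)

    def stride_values(self, side: str, param: str) -> np.ndarray:
        return np.array([s[param] for s in self.feet[side]["strides"]], dtype=float)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "belt_speed": self.belt_speed,
            "fs": self.fs,
            "feet": {
                side: {
                    "tc_times": list(map(float, f["tc_times"])),
                    "midswing_times": list(map(float, f["midswing_times"])),
                    "ic_times": list(map(float, f["ic_times"])),
                    "footflat": [[float(a), float(b)] for a, b in f["footflat"]],
                    "strides": f["strides"],
                }
                for side, f in self.feet.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(feet=d["feet"], mode=d["mode"], belt_speed=d["belt_speed"],
                   fs=d["fs"])


@dataclass
class Kinematics:
    """Sampled trajectories plus the schedule they were built from."""

    time: np.ndarray
    fs: float
    mode: str
    belt_speed: float
    frame_speed: float  # belt speed (treadmill) or pelvis speed (overground)
    feet: dict  # side -> dict of sampled arrays and the cycle schedule
    truth: GroundTruth
    params: GaitSimulationParams


# ---------------------------------------------------------------------------
# waveform primitives


def _minjerk_pos(u):
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _minjerk_vel(u):
    """d/du of the minimum-jerk interpolant; zero value/slope at both ends."""
    out = np.zeros_like(u, dtype=float)
    m = (u > 0) & (u < 1)
    um = u[m]
    out[m] = 30 * um**2 * (1 - um) ** 2
    return out


def _bump(u):
    """Raised-cosine bump on [0, 1], zero value at the ends, unit peak."""
    out = np.zeros_like(u, dtype=float)
    m = (u > 0) & (u < 1)
    out[m] = 0.5 * (1 - np.cos(2 * np.pi * u[m]))
    return out


def _bump_integral(u):
    """Running integral of _bump in units of the bump width."""
    uc = np.clip(u, 0.0, 1.0)
    return 0.5 * (uc - np.sin(2 * np.pi * uc) / (2 * np.pi))


# ---------------------------------------------------------------------------
# schedule


def _draw_schedule(params: GaitSimulationParams, rng: np.random.Generator):
    """Event-time schedule for both feet, plus per-cycle stride lengths.

    The two feet share one stride-time sequence (the right foot is offset by
    half a stride) so that left/right events stay interleaved even at high
    stride-time variability.
    """
    n_cycles = params.n_strides + 1  # one extra cycle -> n_strides full strides
    sd = params.stride_time_cov / 100.0 * params.stride_time_mean
    T = rng.normal(params.stride_time_mean, sd, size=n_cycles + 1)
    T = np.clip(T, 0.5 * params.stride_time_mean, 1.5 * params.stride_time_mean)

    def lengths():
        if params.length_pattern == "stepping_stones":
            lv = rng.choice(np.asarray(params.stepping_levels) / 100.0,
                            size=n_cycles)
            return params.base_stride_length * lv
        return np.full(n_cycles, params.base_stride_length)

    tc_left = params.lead_in + np.concatenate(([0.0], np.cumsum(T[:n_cycles - 1])))
    tc_right = tc_left + 0.5 * T[:n_cycles]
    feet = {}
    for side, tc in (("left", tc_left), ("right", tc_right)):
        dur = np.diff(np.concatenate((tc, [tc[-1] + params.stride_time_mean])))
        swing = params.swing_fraction * dur
        ic = tc + swing
        feet[side] = {"tc": tc, "ic": ic, "swing": swing, "L": lengths()}
    return feet


# ---------------------------------------------------------------------------
# main generator


def simulate_kinematics(params: GaitSimulationParams) -> Kinematics:
    """Build foot trajectories, pitch-rate profiles, marker traces and the
    exact ground truth for one trial."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    sched = _draw_schedule(params, rng)

    t_end = max(s["ic"][-1] for s in sched.values()) + params.tail
    n = int(np.ceil(t_end * params.fs)) + 1
    t = np.arange(n) / params.fs
    fs = params.fs

    # mean progression speed: total programmed displacement over total cycle time
    cycle_speed = {}
    for side, s in sched.items():
        dur = np.diff(np.concatenate((s["tc"], [s["tc"][-1] + params.stride_time_mean])))
        cycle_speed[side] = float(np.sum(s["L"]) / np.sum(dur))
    mean_speed = float(np.mean(list(cycle_speed.values())))
    belt = params.belt_speed if params.belt_speed is not None else mean_speed
    if params.mode == "treadmill":
        frame_speed = belt
    else:
        belt = 0.0
        frame_speed = mean_speed  # pelvis progression speed

    feet_out: dict = {}
    truth_feet: dict = {}
    for side, s in sched.items():
        u_ap = np.zeros(n)  # support-frame AP velocity of the foot
        v_z = np.zeros(n)
        gyro = np.zeros(n)
        ms_times = []
        w1 = VERT_BUMP_S
        for k in range(len(s["tc"])):
            tc, ic, S, L = s["tc"][k], s["ic"][k], s["swing"][k], s["L"][k]
            # AP: minimum-jerk swing
            u_ap += (30.0 * L / S) * _clipped_mj_vel(t, tc, S)
            # vertical: symmetric triple-bump acceleration, first peak at TC
            v_z += _vertical_velocity(t, tc, ic, w1, params.foot_clearance, fs)
            # pitch rate: push-off bump, swing lobe, landing bump
            gyro += -GYRO_PUSHOFF_PEAK * _bump((t - (tc - GYRO_PUSHOFF_S / 2))
                                              / GYRO_PUSHOFF_S)
            t_s = tc + GYRO_PUSHOFF_S / 2
            lobe = np.zeros(n)
            m = (t > t_s) & (t < ic)
            lobe[m] = GYRO_SWING_PEAK * np.sin(np.pi * (t[m] - t_s) / (ic - t_s))
            gyro += lobe
            m = (t >= ic) & (t < ic + GYRO_LANDING_S)
            land = np.zeros(n)
            land[m] = -GYRO_LANDING_PEAK * np.sin(
                np.pi * (t[m] - ic) / GYRO_LANDING_S
            )
            gyro += land
            ms_times.append((t_s + ic) / 2.0)

        vel_world = np.zeros((n, 3))
        vel_world[:, 1] = u_ap - belt if params.mode == "treadmill" else u_ap
        vel_world[:, 2] = v_z
        pos_world = _cumtrapz(vel_world, fs)
        pos_world[:, 0] = -0.10 if side == "left" else 0.10

        heel_ap, toe_ap = _marker_ap_profiles(t, s, frame_speed)
        if params.mode == "treadmill":
            heel_ap = heel_ap - belt * t
            toe_ap = toe_ap - belt * t

        margin_start = max(GYRO_LANDING_S, w1 / 2)
        margin_end = max(GYRO_PUSHOFF_S / 2, w1 / 2)
        ff = [(0.0, s["tc"][0] - margin_end)]
        for ic_k, tc_next in zip(s["ic"][:-1], s["tc"][1:]):
            ff.append((ic_k + margin_start, tc_next - margin_end))
        ff.append((s["ic"][-1] + margin_start, t[-1]))

        strides = []
        for k in range(1, len(s["ic"])):
            st = float(s["ic"][k] - s["ic"][k - 1])
            sl = float(s["L"][k])
            strides.append(
                {
                    "ic_start": float(s["ic"][k - 1]),
                    "ic_end": float(s["ic"][k]),
                    "stride_time": st,
                    "stride_length": sl,
                    "stride_velocity": sl / st,
                }
            )

        feet_out[side] = {
            "pos_world": pos_world,
            "vel_world": vel_world,
            "gyro_ml": gyro,
            "heel_ap_world": heel_ap,
            "toe_ap_world": toe_ap,
            "schedule": s,
        }
        truth_feet[side] = {
            "tc_times": s["tc"].tolist(),
            "midswing_times": ms_times,
            "ic_times": s["ic"].tolist(),
            "footflat": ff,
            "strides": strides,
        }

    truth = GroundTruth(feet=truth_feet, mode=params.mode,
                        belt_speed=float(belt), fs=fs)
    return Kinematics(
        time=t, fs=fs, mode=params.mode, belt_speed=float(belt),
        frame_speed=float(frame_speed), feet=feet_out, truth=truth,
        params=params,
    )


def _clipped_mj_vel(t, tc, S):
    out = np.zeros_like(t)
    m = (t > tc) & (t < tc + S)
    u = (t[m] - tc) / S
    out[m] = u**2 * (1 - u) ** 2
    return out


def _vertical_velocity(t, tc, ic, w1, clearance, fs):
    """Vertical swing velocity from a symmetric triple-bump acceleration.

    Up-bump centred on TC, down-bump spanning mid-swing, up-bump centred on
    IC; amplitudes balance so velocity and net displacement return to zero.
    The profile is scaled so peak foot height equals ``clearance``.  The
    whole profile is advanced by half a sample so that the emitted
    acceleration (a backward difference of sampled velocity, which
    represents the inter-sample midpoint) peaks on the true TC instant.
    """
    half = 0.5 / fs
    tc, ic = tc - half, ic - half
    S = ic - tc
    w2 = S - w1
    r = 2.0 * w1 / w2
    v = (
        w1 * _bump_integral((t - (tc - w1 / 2)) / w1)
        - r * w2 * _bump_integral((t - (tc + w1 / 2)) / w2)
        + w1 * _bump_integral((t - (ic - w1 / 2)) / w1)
    )
    # scale to the requested clearance using the exact same sampled profile
    lo = max(0, int(np.floor((tc - w1) * fs)))
    hi = min(len(t), int(np.ceil((ic + w1) * fs)))
    z = np.cumsum(v[lo:hi]) / fs
    peak = float(np.max(z)) if hi > lo else 0.0
    if peak <= 0:
        return np.zeros_like(t)
    return v * (clearance / peak)


def _cumtrapz(v, fs):
    out = np.zeros_like(v)
    out[1:] = np.cumsum((v[1:] + v[:-1]) / 2.0, axis=0) / fs
    return out


def _marker_ap_profiles(t, sched, frame_speed):
    """Support-frame AP heel and toe positions engineered so the heel's
    descending crossing of ``frame_speed`` falls exactly on each true IC and
    the toe's ascending crossing exactly on each true TC."""
    heel = np.full_like(t, -0.05)
    toe = np.full_like(t, 0.15)
    for k in range(len(sched["tc"])):
        tc, ic, S, L = (sched["tc"][k], sched["ic"][k], sched["swing"][k],
                        sched["L"][k])
        D = _solve_marker_window(S, L, frame_speed)
        # heel: moves over [TC, TC + D]; descending crossing at TC + tau*D = IC
        heel += L * _minjerk_pos((t - tc) / D)
        # toe: moves over [TC - (D - S), IC]; ascending crossing at TC
        t0 = tc - (D - S)
        toe += L * _minjerk_pos((t - t0) / D)
    return heel, toe


def _solve_marker_window(S, L, c):
    """Duration D of a minimum-jerk marker excursion of length L whose
    velocity crosses the frame speed ``c`` on the descending limb exactly S
    after onset.  Falls back to 1.15*S when the frame speed is too high to
    be crossed (degenerate, e.g. c = 0)."""
    if c <= 0:
        return 1.15 * S

    def f(D):
        k = np.sqrt(c * D / (30.0 * L))
        if k >= 0.25:
            return np.inf
        tau = (1 + np.sqrt(1 - 4 * k)) / 2.0
        return tau * D - S

    d_hi = 0.99 * 30.0 * L / (16.0 * c)
    if d_hi <= S or not np.isfinite(f(d_hi)) or f(d_hi) < 0:
        return 1.15 * S
    return float(brentq(f, S, d_hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# recordings


def imu_from_kinematics(
    kin: Kinematics, params: GaitSimulationParams | None = None
) -> tuple[ImuRecording, ImuRecording]:
    """Emit per-foot IMU recordings (earth-frame acceleration, sensor-frame
    pitch rate) with the configured bias, drift and noise.

    Acceleration is the backward difference of the sampled world velocity,
    so the rectangle-rule integrator reproduces the trajectory exactly on
    noise-free input.
    """
    params = params or kin.params
    rng = np.random.default_rng(params.seed + 1)
    out = []
    for side in ("left", "right"):
        v = kin.feet[side]["vel_world"]
        accel = np.zeros_like(v)
        accel[1:] = (v[1:] - v[:-1]) * kin.fs
        accel = accel + params.accel_bias + params.accel_bias_drift * kin.time[:, None]
        if params.noise_accel > 0:
            accel = accel + rng.normal(0.0, params.noise_accel, size=accel.shape)
        gyro = np.zeros_like(v)
        gyro[:, 0] = kin.feet[side]["gyro_ml"]
        if params.noise_gyro > 0:
            gyro = gyro + rng.normal(0.0, params.noise_gyro, size=gyro.shape)
        out.append(
            ImuRecording(
                time=kin.time, fs=kin.fs, gyro_sensor=gyro, accel_earth=accel,
                side=side, gravity_removed=True,
            )
        )
    return out[0], out[1]


def markers_from_kinematics(
    kin: Kinematics, params: GaitSimulationParams | None = None
) -> MarkerRecording:
    """Emit the optical-marker recording (heel/toe/ankle per side, pelvis)."""
    params = params or kin.params
    n = len(kin.time)
    markers: dict = {}
    for side in ("left", "right"):
        foot = kin.feet[side]
        x_ml = foot["pos_world"][0, 0]
        z = foot["pos_world"][:, 2]
        heel = np.column_stack([np.full(n, x_ml), foot["heel_ap_world"], z])
        toe = np.column_stack([np.full(n, x_ml), foot["toe_ap_world"], z])
        ankle = np.column_stack(
            [np.full(n, x_ml), foot["pos_world"][:, 1], z + 0.07]
        )
        markers[side] = {"heel": heel, "toe": toe, "ankle": ankle}
    if kin.mode == "treadmill":
        pelvis_ap = np.full(n, 0.3)
    else:
        pelvis_ap = 0.3 + kin.frame_speed * kin.time
    pelvis = np.column_stack([np.zeros(n), pelvis_ap, np.full(n, 1.0)])
    return MarkerRecording(
        time=kin.time, fs=kin.fs, markers=markers, pelvis=pelvis, mode=kin.mode
    )


def simulate_trial(params: GaitSimulationParams):
    """Convenience wrapper: kinematics -> (imu_left, imu_right, markers,
    truth)."""
    kin = simulate_kinematics(params)
    left, right = imu_from_kinematics(kin)
    markers = markers_from_kinematics(kin)
    return left, right, markers, kin.truth


# ---------------------------------------------------------------------------
# fixture presets

PRESETS = {
    # healthy treadmill walking, regular stride lengths
    "healthy_regular_treadmill": dict(
        stride_time_mean=1.05, base_stride_length=1.32,
        length_pattern="regular", mode="treadmill",
    ),
    # healthy treadmill walking on projected stepping stones (80-120 %)
    "healthy_irregular_treadmill": dict(
        stride_time_mean=1.07, base_stride_length=1.31,
        length_pattern="stepping_stones", mode="treadmill",
    ),
    # slow, variable gait in the stepping-stone condition.  Speed and
    # variability follow stroke-survivor medians; left/right asymmetry of
    # real hemiparetic gait is not modelled.
    "slow_irregular_treadmill": dict(
        stride_time_mean=1.42, base_stride_length=0.78,
        length_pattern="stepping_stones", mode="treadmill",
    ),
    # overground walking at comfortable speed
    "overground_regular": dict(
        stride_time_mean=1.05, base_stride_length=1.30,
        length_pattern="regular", mode="overground",
    ),
}


def make_fixture(name: str, seed: int, outdir, **overrides) -> dict:
    """Write a complete fixture (IMU + marker CSVs, ground-truth JSON,
    parameter echo) for a named preset.  Returns the file paths."""
    if name not in PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = GaitSimulationParams(seed=seed, **{**PRESETS[name], **overrides})
    left, right, markers, truth = simulate_trial(params)
    paths = {
        "imu_left": outdir / "imu_left.csv",
        "imu_right": outdir / "imu_right.csv",
        "markers": outdir / "markers.csv",
        "truth": outdir / "truth.json",
        "params": outdir / "params.yaml",
    }
    write_imu_csv(left, paths["imu_left"])
    write_imu_csv(right, paths["imu_right"])
    write_marker_csv(markers, paths["markers"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
        fh.write("\n")
    with open(paths["params"], "w") as fh:
        yaml.safe_dump({"preset": name, **asdict(params)}, fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}
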