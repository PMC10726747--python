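"""Synthetic gait generator: determinism, ground-truth consistency, and
signal/truth agreement."""

import json

import numpy as np
import pytest

from stridekit import make_fixture, read_imu_csv, read_marker_csv
from stridekit.errors import ParameterError
from stridekit.simulate import (
    GaitSimulationParams,
    imu_from_kinematics,
    markers_from_kinematics,
    simulate_kinematics,
    simulate_trial,
)
from stridekit.spatial import reconstruct_velocity

FS = 100.0


def test_same_seed_is_bit_identical():
    p = GaitSimulationParams(n_strides=10, seed=5, noise_gyro=0.02,
                             noise_accel=0.1)
    a = simulate_trial(p)
    b = simulate_trial(GaitSimulationParams(n_strides=10, seed=5,
                                            noise_gyro=0.02, noise_accel=0.1))
    np.testing.assert_array_equal(a[0].accel_earth, b[0].accel_earth)
    np.testing.assert_array_equal(a[0].gyro_sensor, b[0].gyro_sensor)
    np.testing.assert_array_equal(
        a[2].get("left", "heel"), b[2].get("left", "heel")
    )


def test_ground_truth_self_consistency(trial_stones):
    truth = trial_stones.truth
    for side in ("left", "right"):
        st = truth.stride_values(side, "stride_time")
        sl = truth.stride_values(side, "stride_length")
        sv = truth.stride_values(side, "stride_velocity")
        np.testing.assert_allclose(sv, sl / st, rtol=1e-12)
        # event ordering TC < mid-swing < IC per cycle
        f = truth.feet[side]
        tc = np.asarray(f["tc_times"])
        ms = np.asarray(f["midswing_times"])
        ic = np.asarray(f["ic_times"])
        assert np.all(tc < ms) and np.all(ms < ic)
        assert np.all(np.diff(ic) > 0)


def test_regular_overground_truth_lengths(trial_overground):
    for side in ("left", "right"):
        sl = trial_overground.truth.stride_values(side, "stride_length")
        np.testing.assert_allclose(sl, 1.30, atol=1e-12)


def test_stepping_stone_levels_and_cov(trial_stones):
    """Stride lengths come from the programmed 80-120 % levels and the
    realized length CoV is near the population value of a uniform draw
    (~14.1 %)."""
    base = trial_stones.params.base_stride_length
    levels = np.asarray(trial_stones.params.stepping_levels) / 100.0
    for side in ("left", "right"):
        sl = trial_stones.truth.stride_values(side, "stride_length")
        ratios = sl / base
        assert all(np.min(np.abs(levels - r)) < 1e-9 for r in ratios)
        cov = sl.std(ddof=1) / sl.mean() * 100
        assert 10.0 < cov < 18.0


def test_noise_free_signals_double_integrate_to_truth(trial_regular):
    """Rectangle-rule double integration of the emitted acceleration, with
    the true foot flats as ZUPT anchors, reproduces the programmed
    belt-frame stride lengths within 1 cm."""
    truth = trial_regular.truth
    for rec, side in ((trial_regular.imu_left, "left"),):
        ff = [
            (int(round(a * FS)), int(round(b * FS)))
            for a, b in truth.feet[side]["footflat"]
        ]
        vel = reconstruct_velocity(rec.accel_earth, ff, FS)
        pos = np.cumsum(vel.v_final, axis=0) / FS
        ics = np.round(truth.events(side, "ic") * FS).astype(int)
        dy = np.diff(pos[ics, 1])
        dx = np.diff(pos[ics, 0])
        lengths = np.hypot(dx, dy)
        target = truth.stride_values(side, "stride_length")
        # skip the first stride (integrator not yet anchored)
        np.testing.assert_allclose(lengths[1:], target[1:], atol=0.01)


def test_emitted_bias_is_additive():
    kin = simulate_kinematics(GaitSimulationParams(n_strides=8, seed=9))
    clean, _ = imu_from_kinematics(kin)
    biased, _ = imu_from_kinematics(
        kin, GaitSimulationParams(n_strides=8, seed=9, accel_bias=0.02)
    )
    np.testing.assert_allclose(
        biased.accel_earth - clean.accel_earth, 0.02, atol=1e-12
    )


def test_swing_boundaries_are_smooth():
    """Numerical second derivative of the foot trajectory vanishes at the
    boundaries of each swing's motion envelope (the phase transitions into
    and out of foot flat)."""
    kin = simulate_kinematics(
        GaitSimulationParams(n_strides=10, seed=10, stride_time_cov=0.0)
    )
    from stridekit.simulate import GYRO_PUSHOFF_S, VERT_BUMP_S

    foot = kin.feet["left"]
    accel = np.zeros_like(foot["vel_world"])
    accel[1:] = np.diff(foot["vel_world"], axis=0) * FS
    sched = foot["schedule"]
    margin = max(VERT_BUMP_S / 2, GYRO_PUSHOFF_S / 2) + 0.01
    for tc, ic in zip(sched["tc"], sched["ic"]):
        i0 = int(np.floor((tc - margin) * FS))
        i1 = int(np.ceil((ic + margin) * FS))
        belt_corr = 0.0  # belt speed is constant; acceleration unaffected
        assert abs(accel[i0, 1] - belt_corr) < 1e-3
        assert abs(accel[i1, 1] - belt_corr) < 1e-3
        assert abs(accel[i0, 2]) < 1e-3
        assert abs(accel[i1, 2]) < 1e-3


def test_markers_constant_while_standing(trial_regular):
    """During the quiet lead-in every marker is stationary in the support
    frame (on the treadmill, world positions drift at exactly belt speed)."""
    m = trial_regular.markers
    belt = trial_regular.truth.belt_speed
    t = m.time
    sel = t < trial_regular.params.lead_in - 0.2
    for side in ("left", "right"):
        for name in ("heel", "toe", "ankle"):
            ap = m.get(side, name)[sel, 1] + belt * t[sel]
            assert float(np.ptp(ap)) < 1e-9
            assert float(np.ptp(m.get(side, name)[sel, 2])) < 1e-9


def test_marker_deltas_match_truth(trial_overground, trial_belt12):
    # overground: heel IC-to-IC delta equals the programmed stride length
    # per-stride deltas carry sample-grid noise (the heel passes IC at the
    # frame speed, ~1.2 m/s, so half a sample is ~6 mm); the mean is exact
    truth = trial_overground.truth
    heel = trial_overground.markers.get("left", "heel")[:, 1]
    ics = np.round(truth.events("left", "ic") * FS).astype(int)
    delta = np.diff(heel[ics])
    target = truth.stride_values("left", "stride_length")
    assert float(np.abs(delta - target).mean()) < 0.01
    assert float(np.abs(delta - target).max()) < 0.02
    # treadmill: world-frame delta is ~0; belt-frame delta matches truth
    truth_tm = trial_belt12.truth
    heel_tm = trial_belt12.markers.get("left", "heel")[:, 1]
    ics_tm = np.round(truth_tm.events("left", "ic") * FS).astype(int)
    t_ic = ics_tm / FS
    world = np.diff(heel_tm[ics_tm])
    beltframe = world + truth_tm.belt_speed * np.diff(t_ic)
    assert np.all(np.abs(world) < 0.15)
    np.testing.assert_allclose(
        beltframe, truth_tm.stride_values("left", "stride_length"), atol=0.02
    )


def test_make_fixture_presets(tmp_path):
    paths = make_fixture("healthy_regular_treadmill", seed=3,
                         outdir=tmp_path / "fx", n_strides=8)
    left = read_imu_csv(paths["imu_left"])
    assert left.fs == 100.0 and left.side == "left"
    markers = read_marker_csv(paths["markers"])
    assert markers.mode == "treadmill"
    with open(paths["truth"]) as fh:
        truth = json.load(fh)
    st = np.diff(truth["feet"]["left"]["ic_times"])
    assert abs(np.median(st) - 1.05) < 0.1
    sl = [s["stride_length"] for s in truth["feet"]["left"]["strides"]]
    np.testing.assert_allclose(sl, 1.32, atol=1e-9)

    slow = make_fixture("slow_irregular_treadmill", seed=3,
                        outdir=tmp_path / "slow", n_strides=8)
    with open(slow["truth"]) as fh:
        truth_s = json.load(fh)
    st = np.diff(truth_s["feet"]["left"]["ic_times"])
    assert abs(np.median(st) - 1.42) < 0.15
    sl = [s["stride_length"] for s in truth_s["feet"]["left"]["strides"]]
    assert 0.78 * 0.75 <= np.mean(sl) <= 0.78 * 1.25

    with pytest.raises(ParameterError):
        make_fixture("moonwalk", seed=0, outdir=tmp_path)


def test_make_fixture_is_deterministic(tmp_path):
    a = make_fixture("overground_regular", seed=7, outdir=tmp_path / "a",
                     n_strides=6)
    b = make_fixture("overground_regular", seed=7, outdir=tmp_path / "b",
                     n_strides=6)
    for key in ("imu_left", "imu_right", "markers", "truth"):
        with open(a[key], "rb") as fa, open(b[key], "rb") as fb:
            assert fa.read() == fb.read()


def test_infeasible_parameters_rejected():
    with pytest.raises(ParameterError):
        GaitSimulationParams(swing_fraction=0.1).validate()
    with pytest.raises(ParameterError):
        GaitSimulationParams(stride_time_mean=0.2).validate()
    with pytest.raises(ParameterError):
        GaitSimulationParams(length_pattern="hopscotch").validate()
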