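"""Strapdown integration, drift compensation, ZUPT and stride parameters."""

import numpy as np
import pytest

from stridekit import (
    analyze_imu_trial,
    apply_zupt,
    compute_strides,
    estimate_drift_curve,
    integrate_acceleration,
    integrate_velocity,
    reconstruct_velocity,
    summarize_trial,
)
from stridekit.errors import ParameterError
from stridekit.imu_events import GaitEventSet
from stridekit.spatial import PositionTrace, StrideRecord, StrideTable

FS = 100.0


# ---------------------------------------------------------------------------
# integration oracles


def test_integration_rectangle_rule():
    # zero in, zero out
    np.testing.assert_array_equal(
        integrate_acceleration(np.zeros((50, 3)), FS), np.zeros((50, 3))
    )
    # constant 1 m/s^2 for 1 s at 100 Hz -> exactly 1.00 m/s
    a = np.ones((100, 1))
    v = integrate_acceleration(a, FS)
    assert v[-1, 0] == pytest.approx(1.0, abs=1e-12)
    # linearity
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=(80, 3)), rng.normal(size=(80, 3))
    np.testing.assert_allclose(
        integrate_acceleration(x + y, FS),
        integrate_acceleration(x, FS) + integrate_acceleration(y, FS),
        atol=1e-12,
    )
    with pytest.raises(ParameterError):
        integrate_acceleration(np.array([[np.nan, 0, 0]]), FS)


def test_position_integration_and_ramp_bound():
    # constant 1 m/s for 2 s -> 2.00 m (p measured relative to p[0])
    v = np.ones((201, 3))
    pos = integrate_velocity(v, FS)
    assert pos.p[0, 1] == 0.0
    assert pos.p[200, 1] == pytest.approx(2.0, abs=1e-12)
    # ramp velocity v = t: position error vs T^2/2 within T*Ts/2
    T = 3.0
    t = np.arange(0, T + 1e-9, 1 / FS)
    ramp = np.column_stack([t * 0, t, t * 0])
    pos = integrate_velocity(ramp, FS)
    err = abs(pos.p[-1, 1] - T**2 / 2)
    assert err <= T / FS / 2 + 1e-9


# ---------------------------------------------------------------------------
# drift curve and ZUPT


def _ff(pairs):
    return [(int(a), int(b)) for a, b in pairs]


def test_drift_curve_zero_and_linear():
    ff = _ff([(100, 130), (200, 230), (300, 330)])
    v = np.zeros((400, 3))
    np.testing.assert_array_equal(estimate_drift_curve(v, ff), v)
    # linearly growing bias: PCHIP through collinear anchors is the line
    t = np.arange(400) / FS
    v = np.column_stack([0.02 * t, 0.01 * t, -0.03 * t])
    drift = estimate_drift_curve(v, ff)
    np.testing.assert_allclose(drift, v, atol=1e-9)
    with pytest.raises(ParameterError):
        estimate_drift_curve(v, ff[:1])


def test_drift_curve_monotone_between_anchors():
    """Between anchor plateaus at 0 and 1 the interpolant is monotone
    non-decreasing (sigmoid-like), a defining property of shape-preserving
    PCHIP."""
    ff = _ff([(0, 20), (60, 80), (120, 140), (180, 200)])
    v = np.zeros((200, 1))
    v[100:, 0] = 1.0
    drift = estimate_drift_curve(v, ff)[:, 0]
    assert np.all(np.diff(drift) >= -1e-12)
    assert drift[69] == pytest.approx(0.0, abs=1e-9)
    assert drift[131] == pytest.approx(1.0, abs=1e-9)


def test_zupt_constant_residual_and_identity():
    ff = _ff([(50, 80), (150, 180)])
    v = np.zeros((250, 3))
    np.testing.assert_array_equal(apply_zupt(v, ff), v)
    v2 = np.full((250, 3), 0.1)
    out = apply_zupt(v2, ff)
    for s, e in ff:
        np.testing.assert_allclose(out[s:e], 0.0, atol=1e-12)


def test_zupt_zeroes_foot_flats_with_injected_bias(trial_overground):
    """Noise-free overground trial with 0.02 m/s^2 accelerometer bias:
    after de-drift + ZUPT (anchored on the true foot flats) the mean speed
    over every foot-flat interval is <= 1e-6 m/s."""
    from stridekit.simulate import GaitSimulationParams, simulate_trial

    p = GaitSimulationParams(
        n_strides=20, seed=21, mode="overground", accel_bias=0.02
    )
    left, _, _, truth = simulate_trial(p)
    ff = [
        (int(round(a * FS)), int(round(b * FS)))
        for a, b in truth.feet["left"]["footflat"]
    ]
    vel = reconstruct_velocity(left.accel_earth, ff, FS)
    for s, e in ff:
        assert float(np.abs(vel.v_final[s:e]).mean()) <= 1e-6


# ---------------------------------------------------------------------------
# stride parameters


def _events_with_ics(ics, fs=FS, footflat=None):
    return GaitEventSet(
        side="left", midswing_idx=[], ic_idx=ics, tc_idx=[],
        footflat=footflat or [], fs=fs,
    )


def test_stride_parameters_hand_case():
    n = 300
    p = np.zeros((n, 3))
    p[205:] = (0.60, 1.20, 0.0)
    pos = PositionTrace(time=np.arange(n) / FS, p=p)
    ev = _events_with_ics([100, 205])
    table = compute_strides(pos, ev, first_footflat_end=0.5)
    assert len(table) == 1
    r = table.records[0]
    assert r.stride_time == pytest.approx(1.05)
    assert r.stride_length == pytest.approx(np.sqrt(1.80), abs=1e-9)
    assert r.stride_velocity == pytest.approx(np.sqrt(1.80) / 1.05, abs=1e-9)


def test_velocity_identity_and_first_footflat_exclusion(trial_regular):
    for side in ("left", "right"):
        table = getattr(trial_regular.imu, side).strides
        assert len(table) > 0
        for r in table.records:
            assert r.stride_velocity == pytest.approx(
                r.stride_length / r.stride_time, abs=1e-9
            )
            if not r.valid:
                assert r.exclusion_reason == "before_first_footflat"
        ff_end = getattr(trial_regular.imu, side).events.footflat[0][1] / FS
        for r in table.valid_records():
            assert r.ic_start >= ff_end


def test_fewer_than_two_ics_gives_empty_table():
    pos = PositionTrace(time=np.arange(10) / FS, p=np.zeros((10, 3)))
    assert len(compute_strides(pos, _events_with_ics([5]), 0.0)) == 0


def test_summaries_hand_arithmetic():
    def table_from(values):
        recs = [
            StrideRecord("left", i, i + 1.0, v, v, 1.0) for i, v in enumerate(values)
        ]
        return StrideTable(records=recs)

    s = summarize_trial(table_from([1.0, 1.0, 1.0]))
    assert s["stride_time"]["cov_pct"] == pytest.approx(0.0)
    s = summarize_trial(table_from([0.9, 1.0, 1.1]))
    assert s["stride_time"]["mean"] == pytest.approx(1.0)
    assert s["stride_time"]["sd"] == pytest.approx(0.1)
    assert s["stride_time"]["cov_pct"] == pytest.approx(10.0)
    s = summarize_trial(table_from([1.0, 2.0, 3.0, 4.0]))
    assert s["stride_time"]["median"] == pytest.approx(2.5)
    assert s["stride_time"]["iqr"] == pytest.approx(1.5)
    bad = table_from([1.0, 1.0])
    for r in bad.records:
        r.valid = False
    with pytest.raises(ParameterError):
        summarize_trial(bad)


# ---------------------------------------------------------------------------
# end-to-end recovery properties


def test_overground_stride_length_recovery(trial_overground):
    """Programmed 1.30 m stride length recovered with < 1 cm mean absolute
    error over the valid strides."""
    for side in ("left", "right"):
        sl = getattr(trial_overground.imu, side).strides.values("stride_length")
        assert len(sl) >= 30
        assert float(np.abs(sl - 1.30).mean()) < 0.01


def test_treadmill_frame_property(trial_belt12):
    """On a constant-belt treadmill the ZUPT anchors the belt frame: the
    recovered stride length matches the programmed belt-frame length within
    2 cm even though the world-frame foot displacement differs by
    belt speed x stride time."""
    for side in ("left", "right"):
        sl = getattr(trial_belt12.imu, side).strides.values("stride_length")
        assert abs(float(sl.mean()) - 1.26) < 0.02


def test_drift_compensation_is_doing_work():
    """With constant accelerometer bias, de-drift + ZUPT keeps the
    stride-length error below 5 cm; without them the error exceeds 10 cm."""
    from stridekit.simulate import GaitSimulationParams, simulate_trial

    p = GaitSimulationParams(
        n_strides=40, seed=22, mode="overground",
        base_stride_length=1.30, accel_bias=0.05,
    )
    left, right, _, _ = simulate_trial(p)
    good = analyze_imu_trial(left, right)
    sl = good.left.strides.values("stride_length")
    assert float(np.abs(sl - 1.30).mean()) < 0.05
    bad = analyze_imu_trial(left, right, dedrift=False, zupt=False)
    sl_bad = bad.left.strides.values("stride_length")
    assert float(np.abs(sl_bad - 1.30).mean()) > 0.10
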