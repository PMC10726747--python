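"""Shared simulated trials.

All fixtures are session-scoped so each study condition is simulated and
analysed once for the whole suite.  Seeds are fixed for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pytest

from stridekit import analyze_imu_trial, analyze_reference_trial
from stridekit.simulate import GaitSimulationParams, simulate_trial


def event_errors_ms(detected_s: np.ndarray, truth_s: np.ndarray) -> np.ndarray:
    """Absolute time error (ms) of each detected event vs nearest truth."""
    detected_s = np.atleast_1d(detected_s)
    return np.array(
        [np.min(np.abs(truth_s - d)) * 1000.0 for d in detected_s]
    )


class Trial:
    """A simulated trial plus lazily computed analyses."""

    def __init__(self, params: GaitSimulationParams):
        self.params = params
        (self.imu_left, self.imu_right, self.markers,
         self.truth) = simulate_trial(params)
        self._imu = None
        self._ref = None

    @property
    def imu(self):
        if self._imu is None:
            self._imu = analyze_imu_trial(self.imu_left, self.imu_right)
        return self._imu

    @property
    def ref(self):
        if self._ref is None:
            self._ref = analyze_reference_trial(self.markers)
        return self._ref


@pytest.fixture(scope="session")
def trial_regular():
    """Healthy regular treadmill gait, noise-free, 50 strides."""
    return Trial(GaitSimulationParams(n_strides=50, seed=11))


@pytest.fixture(scope="session")
def trial_noisy():
    """Same condition with sensor noise (gyro 0.05 rad/s, accel 0.2 m/s^2)."""
    return Trial(
        GaitSimulationParams(
            n_strides=50, seed=12, noise_gyro=0.05, noise_accel=0.2
        )
    )


@pytest.fixture(scope="session")
def trial_overground():
    """Noise-free overground walking, programmed stride length 1.30 m."""
    return Trial(
        GaitSimulationParams(
            n_strides=40, seed=13, mode="overground", base_stride_length=1.30
        )
    )


@pytest.fixture(scope="session")
def trial_stones():
    """Stepping-stone (irregular) treadmill gait, 100 strides."""
    return Trial(
        GaitSimulationParams(
            n_strides=100, seed=14, length_pattern="stepping_stones"
        )
    )


@pytest.fixture(scope="session")
def trial_belt12():
    """Treadmill at belt 1.2 m/s with programmed stride length 1.26 m."""
    return Trial(
        GaitSimulationParams(
            n_strides=50, seed=15, base_stride_length=1.26, belt_speed=1.2
        )
    )
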