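"""Signal conditioning applied before event detection and integration.

Defaults follow the validated processing chain: second-order low-pass
Butterworth at 15 Hz for angular velocity and marker positions, 17 Hz for
acceleration.  Filtering is zero-phase (forward-backward) by default so that
event timing is not biased by filter lag; a causal single pass is available
via ``FilterSpec(zero_phase=False)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError

#: package-default cutoffs (Hz) per signal class
GYRO_CUTOFF_HZ = 15.0
ACCEL_CUTOFF_HZ = 17.0
MARKER_CUTOFF_HZ = 15.0

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth settings for one signal class."""

    cutoff: float
    order: int = 2
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")
        if not 0 < self.cutoff < fs / 2:
            raise ParameterError(
                f"cutoff {self.cutoff} Hz must lie in (0, {fs / 2}) Hz at fs={fs}"
            )


def lowpass_butterworth(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Low-pass Butterworth filter along axis 0, preserving length.

    Zero-phase mode applies the filter forward and backward (``filtfilt`` with
    odd-reflection padding), squaring the magnitude response but cancelling
    phase.  Causal mode is a single forward pass with -3 dB at the cutoff.
    """
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ParameterError("signal contains non-finite values")
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def remove_gravity(
    accel_earth: np.ndarray, gravity_removed: bool, g: float = STANDARD_GRAVITY
) -> np.ndarray:
    """Subtract the constant gravity vector (0, 0, g) from earth-frame
    acceleration unless the source already removed it."""
    accel_earth = np.asarray(accel_earth, dtype=float)
    if gravity_removed:
        return accel_earth.copy()
    out = accel_earth.copy()
    out[:, 2] -= g
    return out
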