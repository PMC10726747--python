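# stridekit

Gait analysis from foot-mounted inertial sensors, validated stride-by-stride
against an optical motion-capture reference — with a built-in synthetic gait
simulator so the whole chain can be exercised and tested without laboratory
data.

The package targets rehabilitation researchers and biomechanists who want
spatiotemporal gait parameters (stride time, stride length, stride velocity,
and their variability) from two foot-worn IMUs, on a treadmill or overground,
and who need to know how well those estimates agree with a camera-based
reference system.

## What it computes

**Gait events from the IMU** (per foot, at 100 Hz):

- *mid-swing*: prominent peaks of the mediolateral (pitch) angular velocity
  (`scipy.signal.find_peaks`, peak distance 0.7 s, prominence 1 rad/s);
- *initial contact* (IC): first positive-to-negative zero crossing of the
  mediolateral angular velocity after each mid-swing;
- *terminal contact* (TC): vertical-acceleration peak between consecutive
  mid-swings; with several peaks, the one at the most anti-clockwise angular
  velocity wins;
- *foot flat*: from the contralateral TC to the contralateral mid-swing.

**Spatial reconstruction** by strapdown integration with drift compensation:

    v_raw(t)  = a(t)·Ts + v_raw(t−1)                       (rectangle rule)
    v_dd(t)   = v_raw(t) − drift(t)       drift: PCHIP through foot-flat anchors
    v(t)      = v_dd(t) − v_dd(foot flat)                  (zero-velocity updates)
    p(t)      = v(t)·Ts + p(t−1)

    stride time_n     = t(IC_n) − t(IC_n−1)
    stride length_n   = √(ΔX² + ΔY²) of foot position between the two ICs
    stride velocity_n = stride length_n / stride time_n

On a treadmill the zero-velocity updates anchor the belt frame, so stride
lengths are belt-frame quantities directly comparable to overground values.

**Marker reference**: velocity-based event detection (TC at the anterior
zero crossing of the toe marker's AP velocity, IC at the posterior crossing
of the heel marker's), global coordinates on the treadmill and
pelvis-relative coordinates overground; stride length from heel-position
deltas, plus belt velocity × stride time on the treadmill.

**Agreement statistics**: one-to-one event matching, signed differences
(IMU − reference), mean ± SD with limits of agreement at 1.96 SD,
Bland-Altman point sets per stride and per trial, and per-trial
coefficient-of-variation (CoV = SD/mean·100) comparison.

## Worked example

```sh
stridekit simulate --preset healthy_regular_treadmill --seed 1 --outdir fx
stridekit detect  --left fx/imu_left.csv --right fx/imu_right.csv --outdir out
stridekit validate --imu-left fx/imu_left.csv --imu-right fx/imu_right.csv \
                   --markers fx/markers.csv --outdir val
```

`out/summary.json` then contains, per foot, e.g.

```json
"left": {
  "n_strides": 48, "n_excluded": 2,
  "stride_time":    {"mean": 1.0485, "median": 1.0500, "sd": 0.0150, "cov_pct": 1.43},
  "stride_length":  {"mean": 1.3200, "median": 1.3200, "sd": 0.0000, "cov_pct": 0.004},
  "stride_velocity": {"mean": 1.2591, "median": 1.2572, "sd": 0.0182, "cov_pct": 1.44}
}
```

48 of 50 simulated strides survive (the first strides before the integrator
is anchored by a foot flat are excluded); the recovered stride length matches
the programmed 1.32 m to a fraction of a millimetre, and the stride-time CoV
reflects the programmed 2 % timing variability (mixed across adjacent
cycles).  `val/agreement.json` reports the IMU-vs-reference differences,
here a mean IC difference of −2.8 ms (SD 4.5 ms, limits of agreement −11.7
to +6.0 ms over 102 matched events) and a mean stride-length difference of
−0.0001 m.

The same API is available from Python:

```python
from stridekit import GaitSimulationParams, simulate_trial, analyze_imu_trial

left, right, markers, truth = simulate_trial(GaitSimulationParams(seed=1))
result = analyze_imu_trial(left, right)
print(result.left.strides.summary()["stride_length"]["mean"])
```

## Data formats

Plain CSV with `# key = value` metadata lines and `name[unit]` column
headers (`time[s]` first).  Units are converted on read (deg/s → rad/s,
g → m/s², mm → m); everything internal is SI with X mediolateral,
Y anterior, Z up.  See `docs/methods.md` for the algorithmic details and
design decisions.
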