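# Methods

This note documents the algorithms, the synthetic-data model, the numerical
choices and the known limitations of `stridekit`.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal conditioning

All signals are assumed uniformly sampled (100 Hz default; enforced to
1e-6 s jitter at read time).  A second-order low-pass Butterworth filter is
applied before any analysis: 15 Hz cutoff for angular velocity and marker
positions, 17 Hz for acceleration.  Filtering is zero-phase
(forward-backward, `sosfiltfilt` with odd-reflection padding) by default so
that event timing comparisons against the reference carry no phase lag; a
causal single pass is available per `FilterSpec(zero_phase=False)`.  The
zero-phase pass squares the magnitude response; the single-pass response is
−3 dB at the cutoff.  Earth-frame acceleration may arrive with or without
gravity; the `gravity_removed` flag on the recording decides whether a
constant (0, 0, 9.81) m/s² is subtracted, rather than guessing from the
data.

## IMU event detection

Per foot, on the conditioned signals:

1. **Mounting sign.**  The mediolateral (pitch) gyro sign depends on which
   way the sensor is strapped.  The sign that makes the largest-magnitude
   excursions positive is applied first; all later rules assume swing peaks
   point upward.  Negating both feet's gyros therefore changes nothing
   downstream (tested).
2. **Mid-swing**: positive peaks with prominence ≥ 1 rad/s and ≥ 0.7 s
   separation (`scipy.signal.find_peaks`).  These thresholds suit adult
   walking, where swing peaks reach several rad/s and stride times exceed
   0.7 s.
3. **Initial contact**: the first positive-to-negative zero crossing of the
   pitch rate after each mid-swing, reported as the first sample on the
   negative side (no sub-sample interpolation: the validation grid is
   10 ms).
4. **Terminal contact**: the vertical-acceleration local maximum between
   consecutive mid-swings.  All local maxima are candidates (no prominence
   floor); with several candidates the one at the most negative
   (anti-clockwise) pitch rate is TC, the rest are artefacts.  This makes
   the rule robust to landing-transient acceleration peaks, which coincide
   with near-zero pitch rate.
5. **Foot flat**: from the contralateral TC to the contralateral mid-swing,
   as half-open `[start, end)` sample intervals.  Intervals that would
   overlap an ipsilateral swing indicate broken left/right interleaving and
   are dropped (conservative: cycles are excluded, never re-ordered).

A trial needs at least 3 valid cycles (TC < mid-swing < IC) per foot;
otherwise it is rejected.  The windows before the first and after the last
mid-swing yield no events, so a trial of n strides yields up to n−1 complete
cycles per foot.

## Strapdown reconstruction

Velocity and position use the rectangle-rule recurrence
(v(t) = a(t)·Ts + v(t−1), p likewise), with integration constants zero —
deliberately not trapezoidal, to match the recurrence the event-anchored
corrections are defined on.  Drift is removed in two stages:

- **Drift curve.**  One anchor per foot-flat interval: x = interval
  midpoint, y = interval-mean raw velocity (midpoint + mean is robust to
  residual heel-rock motion at the interval edges).  A shape-preserving
  monotone piecewise cubic (PCHIP) through the anchors is evaluated at every
  sample and subtracted; between anchors it behaves like a smooth sigmoid
  step, which is what slowly accumulating integration drift looks like
  between stationary phases.  Outside the outermost anchors the end cubic
  pieces are extended (the native PCHIP extrapolation): for a constant
  accelerometer bias the anchors are collinear and the extension reproduces
  the exact linear drift, which constant extrapolation would not.
- **Zero-velocity updates.**  Per segment between consecutive foot-flat
  starts, the mean de-drifted velocity over the preceding foot-flat interval
  is subtracted, making velocity exactly zero-mean over every foot flat.
  Samples before the first foot flat carry the first interval's correction;
  strides starting before the first foot-flat end are flagged invalid and
  excluded from summaries, because the integrator is not yet anchored there.

On a treadmill the stationary-relative-to-belt foot moves backward in the
world frame; zeroing its velocity at every foot flat expresses the
reconstruction in the belt frame, so recovered stride lengths are belt-frame
quantities (this is also why the marker reference adds belt velocity ×
stride time on the treadmill).

Stride parameters: stride time between consecutive ICs; stride length as the
horizontal-plane distance √(ΔX²+ΔY²) of the foot position between the two
ICs; velocity as their ratio (an exact identity on every record).  Trial
summaries report mean, median, IQR (linear-interpolation quantiles), sample
SD (n−1) and CoV = SD/mean·100 over valid strides.

## Marker reference

Events follow the velocity-based convention: TC when the toe marker's
anterior-posterior velocity crosses zero anteriorly, IC when the heel
marker's crosses zero posteriorly; +Y is anterior by convention, and a
mirrored walking direction is handled by `anterior_sign=-1`.  Global
coordinates are used on the treadmill, pelvis-relative coordinates
overground.  Velocities are central differences of the 15 Hz-filtered
positions.

Stride length overground is the AP heel-position difference between
consecutive ICs.  On the treadmill, belt velocity is estimated per cycle
from the contralateral stance-foot marker (ankle by default; configurable,
since prose conventions differ on ankle vs foot) between TC + 0.1·swing and
TC + 0.6·swing, and added as belt × stride time.  Instants are resolved to
the nearest sample — no sub-sample interpolation is claimed at 100 Hz — and
the position difference is divided by the elapsed time between the samples
actually used rather than the nominal 0.5·swing: with nearest-sample
rounding the nominal denominator systematically overestimates belt speed by
1-2 % (≈1 cm of stride length), while the elapsed-time form is unbiased and
identical whenever the instants fall on the grid.

## Agreement layer

Events from the two systems are paired by greedy nearest-neighbour matching
within ± half the median reference stride time (any window small relative to
a stride works; the choice is recorded in the report).  On gait-like event
sequences this greedy matching coincides with the optimal one-to-one
assignment, which the tests verify against a Hungarian-algorithm oracle on
200 random instances.  Strides inherit the pairing of their defining ICs.
Reported statistics: signed differences (IMU − reference), mean, sample SD,
limits of agreement at mean ± 1.96 SD, Bland-Altman point sets
(x = mean of methods, y = difference) at stride and trial level, per-trial
CoV per method and their difference, and matched/unmatched counts.
Mixed-model inference is out of scope; the per-stride difference table is
exported so any statistics package can take over.

## Synthetic gait model

The generator builds each foot's trajectory from alternating phases:
foot flat (zero support-frame velocity), a short push-off transition
straddling TC, a smooth swing, and a short landing transition after IC.

- **AP profile**: minimum-jerk displacement over the swing (zero velocity
  and acceleration at both ends, single velocity hump, programmed
  displacement).  On the treadmill the world-frame velocity is the
  support-frame velocity minus a constant belt speed.
- **Vertical profile**: a symmetric triple-bump acceleration (raised
  cosines; up-bump centred on TC, down-bump over mid-swing, up-bump at IC)
  whose amplitudes balance so velocity and net displacement return to zero;
  scaled to the programmed foot clearance (0.08 m default).  Centred on TC,
  the first bump gives the vertical-acceleration signature the TC rule
  detects at the true liftoff instant.  The profile is advanced by half a
  sample because the emitted acceleration is a backward difference of the
  sampled velocity (which represents inter-sample midpoints); without this
  the detected peak would sit one sample late.
- **Pitch rate**: a plantarflexion (negative) bump centred on TC, a
  dominant positive half-sine lobe ending exactly at IC (amplitudes 2.5 and
  3.5 rad/s, so the sign-resolution rule has an unambiguous majority), and
  a small negative landing bump after IC.  True mid-swing is the lobe
  centre.  The landing bump (0.08 s) ends before the contralateral TC
  (~0.1 × stride time after IC at the default 0.4 swing fraction), so
  detected foot flats lie inside truly stationary spans.
- **Markers**: heel and toe are *not* rigid copies of the foot: their AP
  excursions are minimum-jerk windows solved per cycle so that the heel
  crosses the frame velocity (belt speed on the treadmill, pelvis speed
  overground) exactly at the true IC and the toe exactly at the true TC —
  the toe starts moving ~60 ms before TC (early lift during push-off), the
  heel keeps gliding ~60 ms after IC.  The ankle is rigid with the foot
  (stationary in the support frame during stance), which makes the belt
  estimator exact.  The pelvis is a constant-velocity trace; a
  midpoint-of-feet pelvis would oscillate and shift the pelvis-relative
  zero crossings off the true events by design, so the simplification is
  deliberate.
- **Timing**: one shared stride-time sequence (Gaussian, programmed mean
  and CoV, clipped at ±50 %) with the right foot offset by half a stride,
  keeping events interleaved at any variability.  Stepping-stone trials
  draw each stride length from {80, 90, 100, 110, 120} % of the base length
  (population CoV ≈ 14 %).  Two seconds of quiet standing precede the first
  push-off.
- **Sensors**: earth-frame acceleration is emitted as the backward
  difference of the sampled world velocity — so rectangle-rule integration
  reproduces the trajectory exactly on noise-free input — plus optional
  constant bias, linear bias ramp, and white Gaussian noise; the gyro's
  mediolateral channel carries the pitch rate plus noise.  All randomness
  flows from one seeded generator; identical parameters give bit-identical
  trials.

Presets: healthy regular treadmill (stride time 1.05 s, length 1.32 m),
healthy irregular treadmill (1.07 s, 1.31 m base, stepping stones), a
slow/variable stepping-stone preset (1.42 s, 0.78 m — stroke-like speed and
variability only; hemiparetic left/right asymmetry is not modelled), and
regular overground (1.05 s, 1.30 m).  Preset fixtures are noise-free by
default; noise and bias levels are explicit study conditions.

### What the simulator does and does not show

The generator reproduces the signal *morphology* the detection rules assume
(single dominant swing peak, acceleration transients at the contacts,
genuinely stationary foot flats) with exact ground truth, which is what
makes it a useful oracle for the pipeline's logic, drift compensation and
agreement layer.  It does not emulate soft-tissue artefact, orientation
estimation errors (earth-frame acceleration is taken as given), belt-speed
fluctuations of a self-paced treadmill, turning, shuffling or festinating
gait, or marker occlusion/relabelling.  Passing tests therefore validate
the algorithmic chain, not the field performance of the sensors.

Per-stride marker deltas carry ±1 sample of grid noise (the heel passes IC
at roughly the walking speed, so half a sample is ~6 mm); construction
guarantees trial means, and per-stride tolerances in the tests reflect
that.

## Numerical details and degenerate inputs

- 0-based sample indices; foot-flat intervals half-open [start, end);
  events reported on the sample grid.
- Drift estimation needs ≥ 2 foot-flat intervals, summaries ≥ 2 valid
  strides; fewer raise errors rather than returning silent NaNs.
- All-zero gyro traces, non-uniform time stamps, missing columns and
  unknown units are rejected at the boundary (typed exceptions).
- ZUPT residual tolerance: mean |v| ≤ 1e-6 m/s over every foot flat on
  noise-free input (exercised in the tests with an injected constant bias).
- CoV requires a nonzero mean; sample SD uses the n−1 denominator
  throughout.

## Limitations

- Only foot-mounted sensors are analysed; trunk/sacrum channels, stance
  sub-phases beyond foot flat, step (as opposed to stride) parameters, foot
  clearance and turning metrics are out of scope.
- The belt-frame equivalence assumes a constant belt speed during each
  stride; strongly varying self-paced belts would need the variable-speed
  extension.
- Force-plate reference events and C3D marker files are not supported
  (plain-text marker CSV only; C3D is an extension point).
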