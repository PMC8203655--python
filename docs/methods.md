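# Methods

This note documents the models, conventions, numerical choices and
known limitations behind `headtrack`. It is the reference for *why* the
pipeline does what it does; the README covers *what* it does.

## Conventions

* Quaternions are scalar-first `(w, x, y, z)`, Hamilton convention,
  right-handed frames. A pose quaternion maps body coordinates to world
  coordinates. Quaternion streams are hemisphere-aligned (sign-flipped
  whenever consecutive dots are negative) before differentiation or
  interpolation; without this the double cover corrupts q̇.
* World frames are z-up; gravity is (0, 0, −1). The calibrated body
  frame has x forward (mean locomotion direction), y left, z up.
  Positive roll is rightward, positive pitch forward, positive heading
  azimuth rightward, positive elevation upward.
* Timestamps are seconds relative to stream start. Angles are reported
  in degrees; internal math is in radians.
* On-disk formats are plain CSV with a JSON sidecar for metadata
  (frame label, wheel circumference and counter). See `io_model`.

## Kinematic derivation

Velocities are derived, not trusted from the device, so that device and
gold standard pass through the identical numerical path: after time
alignment the device stream is resampled onto the gold-standard grid
and *both* streams are differentiated there. Differentiation uses
`numpy.gradient`'s three-point Lagrange weights (second-order on
non-uniform grids, second-order one-sided at the ends). The truncation
error is O((Ω h)²/6) relative — about 10⁻⁶ at 50 Hz for head-motion
rates — and cancels between the two streams wherever they agree.

Angular velocity is `ω = Im(2 q* q̇)`, the body-frame rate; a
world-frame rate, when needed, is `rot(q, ω)`.

The yaw-difference formula `Δγ = arccos(2⟨q̂_γ, q_γ⟩² − 1)` and the
vector-angle formulas are evaluated in half-angle `atan2` form, which
is algebraically identical but keeps full precision near zero — the
`arccos` form bottoms out around 10⁻⁶ degrees, which would mask the
pipeline's exact-cancellation property.

Heading azimuth uses the two-argument arctangent `atan2(−v_y, v_x)`
rather than the single-argument `−arctan(v_y/v_x)`: the two agree on
forward motion, but only the former is well-defined when walking
backwards.

## Time synchronization

The cross-correlation uses the raw (un-demeaned) sliding dot product of
angular-velocity norms, on a common uniform grid at the coarser of the
two native rates; a demeaned mode exists but is off by default. The
search is limited to ±10 s and requires at least 2 s of overlap per
candidate lag. Only a constant clock offset is modeled (no rate drift).
Tap detection for wheel runs is automated: global maximum of the
high-pass-filtered (4th-order Butterworth, 10 Hz) accelerometer norm
within the search window, required to exceed 3× the window's median
absolute deviation.

## Interpolation

Positions and velocities interpolate linearly. Orientations use squad
(spherical quadrangle) interpolation with inner control points
`s_i = q_i exp(−(log(q_i⁻¹q_{i+1}) + log(q_i⁻¹q_{i−1}))/4)`, endpoint
control points equal to the endpoints; this is C¹ and collapses to
slerp on geodesic data. Outputs are renormalized; extrapolation is an
error.

## Frame calibration

* **World registration (Ŵ→W):** closed-form least squares over the
  first 30 s of the task via SVD of the cross-covariance with
  determinant correction, *without* scale. Scale is excluded
  deliberately: the device's scale misestimation is a primary outcome
  (it *is* TLE and SpE), and absorbing it during registration would
  erase the effect being measured. Degenerate (near-collinear) windows
  are rejected.
* **Calibrated frames (B→C, B̂→Ĉ):** rotation-only least-squares
  attitude (Wahba) solutions with equal weights and the same
  determinant-corrected SVD. The device frame is solved against the
  constraints {v_i/‖v_i‖ → +x, g_i/‖g_i‖ → −z} using instantaneous
  samples (a mean-vector mode is available); the gold-standard frame is
  then solved by pairing its body-frame heading/gravity samples with
  the device's calibrated ones, which makes the two calibrations
  exactly consistent when the streams agree. Samples with gold
  horizontal speed below 0.1 m/s are excluded from heading constraints
  (heading is undefined at rest), and a mean heading within 10° of the
  gravity axis is rejected as ill-conditioned.
* The 30 s window is long enough for robust estimation yet short enough
  that drift inside it stays negligible. Its side effect: any yaw drift
  accumulated up to mid-window (≈ r·t_mid) is absorbed into the world
  rotation, so the measured yaw drift rate under-reads the injected
  rate by roughly t_mid/T — one reason drift experiments need long
  trajectories (below).

## Metrics: denominators, exclusions, edge cases

* RTE and RYE average over the n−k valid windows; with k = 50 at 50 Hz
  the window is ≈ 1 s.
* Trajectory length sums earth-horizontal displacement; any consecutive
  pair implying more than 5 m/s is treated as a re-localization
  artifact and contributes nothing (counted).
* The Δγ percentile exclusion (outside the 1st–99th percentile,
  per-trajectory) is applied before AYE, RYE and YDr; YDr uses the last
  retained sample over the trajectory duration in hours.
* TDr is primarily percent of gold trajectory length (‖p̂_n − p_n‖/L);
  a per-duration variant in m/h is reported separately as `TDr_rate`
  rather than silently reconciling the two conventions.
* Velocity metrics exclude samples with gold horizontal speed below
  0.1 m/s (relative errors diverge at rest); zero-norm vectors are
  additionally excluded from direction terms. Every exclusion is
  counted in `n_excluded` and logged.
* Angle differences (θ, α) are wrapped to (−180°, 180°] before
  averaging.

## Statistics

Quartiles use linear interpolation between order statistics (the common
plotting default). The KDE is the plain fixed-bandwidth Gaussian sum,
default h = 0.2 m/s for speed distributions. The repeated-measures
ANOVA is the classical within-subject decomposition — each effect
tested against its own subject-interaction mean square — implemented
directly in numpy (and cross-checked against statsmodels' `AnovaRM` in
the test suite); no sphericity correction by default, with a
Greenhouse–Geisser mode available. Post-hoc comparisons are two-sided
paired t-tests with Bonferroni correction over the number of pairs,
then halved to a one-sided value whose direction follows the sign of t.
The halving is an unusual convention retained deliberately; a standard
two-sided mode exists for sensitivity analysis.

## The simulator: what it does and does not emulate

`synthetic` generates a rounded-rectangle circuit walked at a constant
task speed (slow walk 0.9, walk 1.4, run 2.2 m/s — inside the median
ranges such studies report), with deterministic gait oscillations
(2 Hz step frequency; 3 cm vertical bob; 5°/3°/2° yaw/pitch/roll sway)
and a stationary lead-in of five slow nods and five slow shakes (0.5 Hz,
20°) for synchronization. Default sampling: 200 Hz device pose,
62.5 Hz device IMU, 50 Hz optical gold standard, 100 Hz wheel IMU. The
truth is generated on the device grid and the gold standard is its
exact 50 Hz subsample, so a zero-error device must produce exactly zero
metrics — the pipeline's identity test.

The error model applies, in fixed order: scale about the start point →
accumulating yaw rotation → band-limited Gaussian position/orientation
noise (default 1 Hz bandwidth: SLAM output is smooth, and white noise
at 200 Hz would unrealistically dominate path-length integration) →
Poisson-timed horizontal re-localization jumps (optionally partially
reversing accumulated offset, mimicking loop closure) → resampling to
the device rate → clock offset → expression in a rotated/translated
device world frame → head-mount rotation of the body frame. The default
world rotation is yaw-only, matching devices that gravity-align their
world frame internally (wheel runs, which have no pose gold standard to
register against, rely on this); full 3-D world rotations are exercised
explicitly in the frame-recovery tests.

`generate_study` links the defaults to conditions: scale factors shrink
with environment size (tracking space 1.01, hallway 0.99, lobby 0.965,
courtyard 0.92 — landmarks recede, stereo disparity drops) and drift
and noise grow with task speed (4/10/25 °/h, 4/6/12 mm). These defaults
exist so the study-level sign patterns (deeper speed under-estimation
in larger environments, larger windowed errors at higher speeds) are
present by construction and can be asserted qualitatively.

What the gait model does **not** emulate: biomechanical variability,
speed fluctuation within a task, curved-path wheel under-reading,
feature-dependent tracking failure, IMU bias/random-walk. Passing
tests therefore demonstrate the correctness of the *evaluation
machinery* under controlled error injection — not the performance of
any real tracker, which must be measured on real recordings.

## Problem sizes of the validation experiments

The standard cells simulate ~50–60 s of locomotion (plus the ~21 s sync
segment), enough for every metric and the calibration windows. Yaw
drift recovery alone uses 2400 s of simulated walking: the measured
rate under-reads the injected one by ≈ 1% (99th-percentile truncation)
plus ≈ t_mid/T (calibration-window absorption, t_mid ≈ 35 s), so a
long trajectory is needed before the bias falls below the 2% target.
The ANOVA null-calibration uses 2000 simulated 9-subject × 3-condition
tables. Study-pattern checks use 4 subjects × 3 tasks × 4 environments.

## Known limitations

* Constant clock offset only; no clock-rate drift or jitter.
* The device's natively reported velocities are ignored; both streams
  are differentiated from pose for symmetry.
* The marker-to-device lever arm is not modeled (positions are treated
  as the same physical point).
* Wheel-based speed comparison inherits the physical differences of the
  two measurements (filtered wheel rate vs differentiated positions),
  so even a perfect device does not produce exactly zero wheel-run
  errors — agreement is at the 10⁻²–10⁻¹ % level rather than machine
  precision.
* YDr on short recordings is dominated by orientation noise (a few
  degrees of final yaw error over a hundredth of an hour is hundreds of
  °/h); interpret drift rates only on long recordings.
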