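# Methods

This note documents the models, parameter choices and known limits of the
`freewheel` toolkit.

## Head-tilt interface

**Model.** A head-worn 3-axis accelerometer at rest measures only gravity.
The inclination angles are the arctangents of each horizontal axis against
the magnitude of the other two, giving pitch θx and roll θy in [−90°, +90°].
The estimate is scale invariant (only the direction of the measured vector
matters) and assumes *static* poses: linear acceleration of the head or
chair biases it, and no gyroscope fusion is attempted.  A zero denominator
returns ±90° by the numerator's sign; the all-zero vector is rejected as
degenerate rather than defaulting to an angle.  Degrees use the exact 180/π
conversion.

**Cubic map.** Each angle maps to a voltage through
v = m·(θ − r)³/s + v_ref, clamped to [0, 5] V.  The map acts on the
*angles in degrees* (not raw accelerations): r and s therefore carry angle
units, and division by s was chosen so that a larger scale factor flattens
the curve.  Defaults m = n = 2.5, r = 0°, s = 30³ deg³, v_ref = 2.5 V put
saturation at a 30° tilt — a comfortable deliberate head excursion — while
|θ| ≤ 5° moves the output by less than 12 mV, an effective dead zone.  All
parameters are per-user configurable, including per-axis sign flips for
users who prefer tilting down for forward.

**Direction classing.** A tilt is neutral while both centred angles sit
inside `dead_zone_deg` (default 10°); otherwise the axis with the larger
absolute centred angle decides (up → forward, down → backward, right/left →
turns), with dominance ties resolved to the pitch axis.

## Eye-gesture interface

**Conditioning.** Each reflectance channel passes an EMA smoother
(y(n) = w·x(n) + (1−w)·y(n−1), default w = 0.2) and then a DC blocker
(y(n) = x(n) − x(n−1) + α·y(n−1), default α = 0.95, stable for α ∈ (0,1)).
Filter defaults are design choices; the DC blocker's previous-input state
seeds from the first sample by default to suppress the start-up transient
on offset signals.  Windows are fixed, non-overlapping, and exactly
round(50 Hz × 1.5 s) = 75 samples per channel; classification on sliding or
triggered windows was not implemented.

**Classifier.** Features are the raw concatenated filtered samples (left
then right, 150 values), standardized per feature with training-set
statistics stored on the model.  The network is deliberately small — 10
tanh hidden units, 4 softmax outputs — trained by full-batch gradient
descent on cross-entropy (fixed step 0.5, 400 epochs, weights initialized
N(0, 1/√fan_in) from the training seed).  Training is a pure function of
(dataset, seed).  The input encoding, activations and optimizer are design
choices made here; alternatives (spectral features, momentum methods) were
not needed at this problem size.  Ties in the output scores break by the
fixed label order (open, close, left, right).

**Sequence decoding.** Two consecutive non-idle gestures form a command
pair; only four pairs map to motion (left,left; right,right; right,close;
left,close) and every other pair resets silently, so isolated
misclassifications cannot move the chair.  "Open" is treated as the idle
gesture; a pending first gesture expires after more than `timeout_windows`
(default 3) idle windows.  The pairing protocol and timeout are design
choices.

## Voice interface

The eight-word grammar is a two-state machine: an attention word (stop,
move, go, run) arms a mode — halt, 1 s timed, 2 s timed, continuous — and
the next orientation word (forward, backward, left, right) fires a drive
command in it.  Orientation words with nothing armed are ignored (spurious
recognizer output must not move the chair) and a second attention word
replaces the first (self-correction).  "Stop" always halts and clears.  In
session timelines, timed commands deactivate after their duration and any
new command supersedes a still-active one.  Acoustic recognition itself is
out of scope; recognizer failures are modelled in the synthetic token
stream by independent per-token drop and confusion probabilities.

## Synthetic signals

The generators define the operating conditions for all tests:

* **IMU traces** follow a static-gravity model: for scripted target angles,
  ax = sin θx, ay = sin θy, az = √(1 − ax² − ay²) (unit norm), with linear
  angle ramps over 0.2 s at segment boundaries and i.i.d. Gaussian axis
  noise.  Target pairs with sin²θx + sin²θy > 1 are rejected as unreachable
  static poses.  No linear acceleration, vibration or gyroscope drift is
  emulated, so passing tests certify the geometry, not robustness to
  dynamic motion.
* **IR gesture windows** are a 2.0 V baseline plus 0.001 V/sample drift,
  a flat-top "saccade–hold–return" pulse (15-sample plateau centred at
  sample 37, 4-sample cosine shoulders, ±0.8 V), and 0.05 V Gaussian noise.
  Left/right gestures deflect the two channels antisymmetrically, close
  deflects both, open stays at baseline; which channel responds positively
  to which gaze direction is an arbitrary, flippable convention.  With
  these defaults the pairwise class-mean distances exceed
  10·σ·√window_len, so the ≥95 % accuracy property is comfortably
  achievable; real recordings with ambient-light variation would be far
  harder, and the classifier's accuracy here says nothing about that case.
  The default dataset is 50 windows per gesture (200 total), each drawn
  from its own child seed of the master seed.
* **Voice streams** emit scripted tokens with independent drop/confusion
  noise.

## Simulator and safety gate

Unicycle kinematics (heading updated before position each step, heading
normalized to (−π, π]) is sufficient for skills-course geometry; mass,
slip and slope dynamics are not modelled.  One voltage channel drives
linear speed and the other angular speed, both linear and odd about 2.5 V,
with a swap flag since the physical channel assignment is a configuration
matter.  The anti-collision gate inhibits only *forward* velocity, when any
obstacle's boundary (centre distance minus radius) lies within 1.2 m and
its bearing falls inside a ±30° forward cone — turning and reversing remain
available so the user can always maneuver away.  The cone width and
forward-only behaviour are design choices for a two-front-sensor layout.
Default integration step 0.05 s, v_max 1 m/s, ω_max π/2 rad/s.

## WST scoring

Fifteen skills scored 0/1/2; total capacity = 100·Σ/(2·n).  Printed
capacities truncate (not round) toward zero at one decimal — 26/30 prints
86.6 — implemented in integer arithmetic ((1000·Σ)//(2n) tenths) so no
floating-point artifact can flip a digit; the exact percentage is kept
alongside.  The denominator generalizes to 2·n for other sheet sizes.  The
toolkit reproduces only the scoring arithmetic; administering the test, and
its performance/confidence subscales, are out of scope.

## Reproducibility and problem sizes

Every stochastic component is a pure function of its inputs and a seed; a
single master seed fans out to named per-module streams via spawned seed
sequences.  The test suite trains the classifier on 10-window-per-class
datasets (fast, same separability regime) while the acceptance script uses
the full 50-per-class default over five dataset seeds; both finish in
seconds on one core.
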