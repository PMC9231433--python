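# freewheel

A hands-free wheelchair interface toolkit for assistive-technology research.
People with severe upper-limb impairments cannot use a power wheelchair's
joystick; `freewheel` implements, simulates and scores three alternative
input channels that replace it:

* **head tilt** — a worn 3-axis accelerometer reads the gravity projection,
  from which the head inclination angles are recovered as

  θx = atan(ax / √(ay² + az²)),  θy = atan(ay / √(ax² + az²)),

  each in [−90°, +90°].  A cubic map with a flat "dead zone" converts the
  angles to the two 0–5 V joystick-replacement voltages,

  v = m·(θ − r)³ / s + 2.5 V (clamped to [0, 5] V),

  so small involuntary movements leave the chair still while deliberate
  tilts ramp the voltage smoothly;
* **eye gestures** — two infrared-reflectance channels sampled at 50 Hz are
  smoothed by an exponential moving average, y(n) = w·x(n) + (1−w)·y(n−1),
  high-passed by a DC blocker, y(n) = x(n) − x(n−1) + α·y(n−1), and cut into
  1.5 s windows (75 samples/channel).  A two-layer feed-forward network
  (10 tanh hidden units, 4 softmax outputs) classifies each window as
  *open*, *close*, *left* or *right*; gesture **pairs** decode to motion
  (left,left → left; right,right → right; right,close → forward;
  left,close → backward; anything else → no action);
* **voice commands** — an eight-word attention/orientation grammar:
  *stop / move / go / run* arm a motion mode (halt, 1 s, 2 s, continuous)
  and *forward / backward / left / right* fire it.

A closed-loop unicycle simulator consumes the voltages (linear speed and
turn rate, odd about the 2.5 V rest point), integrates planar kinematics,
and enforces an ultrasonic anti-collision gate that inhibits forward motion
whenever an obstacle boundary lies within 1.2 m inside a ±30° forward cone.
Driving performance is scored with the Wheelchair Skills Test (WST):
15 skills rated 0/1/2, total capacity = 100·Σscores/(2·n_skills).

All sensor inputs can be synthesized (seeded, reproducible) so every
pipeline runs end to end with no hardware.

## Worked example

Score a WST sheet and run the head pipeline:

```
$ freewheel fixtures --seed 0 --out demo
$ freewheel wst-score --sheet demo/wst_sheet.csv
total capacity: 93.3%
```

The sheet holds the 15 per-skill scores 2,2,2,1,2,1,2,2,2,2,2,2,2,2,2;
they sum to 28 of 30 possible points, and 100·28/30 = 93.33…% prints as
93.3% under the one-decimal truncation convention.

```python
>>> import freewheel as fw
>>> angles = fw.tilt_from_accel(fw.AccelSample(0.5, 0.0, 0.8660))
>>> round(angles.theta_x, 2), round(angles.theta_y, 2)
(30.0, 0.0)
>>> volts = fw.cubic_map(angles)
>>> round(volts.vx, 3), round(volts.vy, 3)
(5.0, 2.5)
```

A 30° forward head tilt recovers θx = 30° from the gravity vector and, with
the default map (m = 2.5, r = 0, s = 30³), saturates the forward channel at
5 V — 30° is full speed; 15° would give 2.8125 V, barely off rest.

Other subcommands: `head-run` (accel CSV → voltage CSV), `eye-train` /
`eye-run` (train the gesture network on a labelled window directory, then
decode a trace), `voice-run` (token stream → activation timeline), `course`
(voltages + course JSON → trajectory CSV).

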