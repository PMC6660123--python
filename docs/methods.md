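# Methods

## System model

posturekit models the computational pipeline of a neck-worn posture
corrector. A triaxial accelerometer rides across the back of the neck with
its x-axis along the spine, y-axis lateral and z-axis anteroposterior. For a
stationary wearer the reading is the projection of unit gravity:

```
ax = cos(pitch)·cos(roll)      ay = sin(roll)      az = −sin(pitch)·cos(roll)
```

with pitch forward-positive and roll left-positive, both in [−90°, 90°].
Upright reads (1, 0, 0) G; a forward slouch lowers `ax` toward cos(pitch); a
leftward tilt raises `ay`, a rightward tilt lowers it. This axis convention
is an assumption of the package, fixed from the device's observed signal
directions (upright `ax` near 1 G, forward tilt descending, leftward roll
raising `ay`); the hardware documentation gives the mounting only
pictorially.

Only `ax` and `ay` enter assessment; `az` is carried through file formats
untouched.

## Signal filtering

Each axis is smoothed with a trailing moving average of the current reading
and the previous nine (window 10 at the default 10 Hz sampling, i.e. a 1 s
memory). Before ten samples exist, all available samples are averaged
(`window_fill` < 10), keeping output aligned index-for-index with input from
the first reading; the alternative of emitting nothing during warm-up would
desynchronize the keypoint and accelerometer streams during calibration.
The filter is linear, shift-equivariant after warm-up, and bounded by the
window extrema; the default session trace is 100 samples (10 s), treating
the device's "initial read plus 99 repeats" as 100 total.

## Thresholds and hysteresis assessment

Per-wearer standard values `S_x`, `S_y` anchor six thresholds (see the
README for the formulas). The trigger margins are 0.01159 G (forward) and
0.02834 G (lateral): the minimum absolute change `|standard − measured|`
across the packaged clinician-labeled measurements of three users, per
direction class — the minimum, rather than the mean, makes the assessment
deliberately strict, so even the smallest labeled tilt tendency alerts. The
release margins 0.00854 G and 0.02441 G are stored verbatim as calibrated
device constants; they are close to, but not exactly, trigger − 0.003 /
0.004, and the printed constants are treated as authoritative rather than
recomputed.

Each direction has a two-threshold comparator. Polarity is derived from the
sign of `href − lref`: the left comparator trips when its input rises past
`href` (trigger above release), the forward and right comparators when the
input falls (trigger below release). Inside the open band the output holds —
no chattering. All comparators start at 0: posture is presumed correct at
session start, which is safe because calibration immediately precedes
assessment. If both lateral comparators ever report 1 (possible only with
pathological, overlapping bands), the side toward which `A_y` actually
deviates from `S_y` wins; a physical tilt cannot be left and right at once.
No backward-tilt comparator exists: a reading above `S_x` never alerts.

Flags map to LEDs (middle ⇔ no flags; top/left/right per flag) and to
messages composed forward-first (`Too Forward & Left!!`, `Too Right!!`).
Reminders repeat while posture stays poor, throttled to one event per
`T0 / warning_time` seconds with `T0 = 10 s`; the device's `warning_time`
setting has no documented units, so "higher value → higher frequency" is
realized as this reciprocal mapping with `T0` configurable. A change of the
flag set while poor re-emits immediately; an empty flag set resets the
throttle.

## Calibration

**Auto-calibration (primary).** A keypoint stream (head, neck, shoulders in
2-D world coordinates, v up) certifies posture geometrically: the head–neck
segment within `tol_deg` of vertical (side profile), then the shoulder
segment within `tol_deg` of horizontal (frontal profile), in that phase
order. `tol_deg` defaults to 2° — strict enough that the captured standard
reflects near-ideal posture, loose enough to terminate under realistic
keypoint noise. A check must hold for `hold_frames = 5` consecutive frames
(0.5 s at 10 Hz) before the standard is sampled, preventing calibration on a
transient frame; the standard is the filtered value at the qualifying
instant, not an average over the hold window. Streams ending before both
phases complete return a partial result with an explicit status, not an
exception. Keypoint times are matched to the nearest filtered sample.

**Sliders (secondary).** Integer sliders a–d in [1, 300] rescale `S_x`
(a/150), the forward margins (b/150), `S_y` (c/150) and the lateral margins
(d/150). The threshold set stores base standards and margins and derives all
thresholds as properties, so slider application is non-compounding and
idempotent by construction: a slider position always maps to the same state
regardless of adjustment history. (Read literally, the device's update
formulas would compound on repeated use; that reading is rejected because it
makes the phone-UI slider position ambiguous.)

## Synthetic wearer

A maneuver is an ordered list of segments, each holding or linearly ramping
to a target pitch/roll — linear interpolation being the simplest trajectory
consistent with the monotone tilt ramps the device exhibits. Readings are
the gravity projection of the interpolated body angles plus:

* i.i.d. Gaussian sensor noise, default σ = 0.005 G per axis when still —
  small relative to the 0.01159 G forward margin, as a resting MEMS
  accelerometer is;
* an optional walking perturbation, a 0.05 G sinusoid at 2 Hz on `ax`
  (walking disturbs the spine axis most), which the 1 s moving average
  attenuates strongly (the window spans two full gait cycles);
* constant mounting-pitch/mounting-roll offsets modeling a wearer whose
  neutral reading is away from the ideal (1, 0) G, as real fittings and body
  shapes show. These act on the sensor only; the camera sees the body, so
  keypoints are generated from the body angles alone. This is what makes
  per-wearer calibration necessary and testable.

Ground truth records the body angles and posture flags under an explicit
angle criterion (default: a tilt beyond 5° is poor posture). Traces are
deterministic given the seed.

The simulator does **not** model biomechanically realistic spine kinematics,
accelerometer bias or temperature drift, keypoint-detector dropouts, or
rotational (gyroscope) dynamics. Tests passing on simulated wearers
therefore demonstrate the correctness of the filtering/threshold/hysteresis
logic and the calibration workflow, not robustness to real-world sensor
artifacts.

## Sessions

`run_session` executes the workflow in device order: keypoint
auto-calibration, then an assessment loop over the filtered trace with timed
setting signals (connect/disconnect, slider and warning-time updates, direct
standard overrides) applied at their timestamps. Reminders are emitted only
while a phone is connected and are not buffered while disconnected — on
reconnect during sustained poor posture the next reminder fires at the next
assessed sample. Comparator outputs are carried across threshold updates.
The log is append-only, time-ordered JSONL and replays byte-for-byte given
identical inputs. The operating duration defaults to 8 h (a workday) and is
always overridden in tests.

The three-device TCP exchange of the original system is modeled as
in-process timed signal scripts speaking a one-line-per-signal text
protocol (`<kind> [value]`); this preserves the connection-gated reminder
contract while keeping everything testable without networking.

## Numerical and test-size choices

* Threshold offsets are compared at 1e-12 absolute in tests; all derived
  threshold arithmetic is plain float64.
* The hysteresis oracle check replays 10⁴-step Gaussian random walks per
  comparator against an independently written two-threshold loop.
* Parameter recovery uses 50 simulated wearers (mounting pitch up to 18°,
  roll up to ±11.5°, σ = 0.01 G) and requires median absolute recovery error
  below 0.01 G per standard; end-to-end detection runs the
  calibrate/tilt/straighten maneuver across 20 seeds. These sizes exercise
  the stochastic behavior while keeping the full suite around one second.
* Degenerate inputs fail loudly: empty traces, non-monotonic timestamps,
  coincident keypoints, `href = lref` bands, out-of-range sliders and
  malformed CSV rows (reported with line numbers) all raise typed errors.
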