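# posturekit

A hardware-free, fully tested model of a **smart-necklace posture correction
system**. The device this package models is a neck-worn triaxial
accelerometer (an MPU-6050-class part) that watches the projection of gravity
onto the wearer's spine (x) and lateral (y) axes, compares the filtered
signals against per-wearer thresholds, and sends throttled "poor posture"
reminders to a phone — the operational signature of kyphosis (forward head
posture) is a drop in the x-axis gravity component, and of a lateral tilt a
shift in the y-axis component.

posturekit is for engineers and researchers in wearable health sensing who
want to study, test or extend the algorithmic core of such a device without
any hardware: every input the pipeline needs can be produced by the built-in
synthetic wearer simulator.

## The model

Raw readings are smoothed with a 10-sample trailing moving average (the
current reading plus the previous nine, at 10 Hz). Per-wearer **standard
values** `S_x`, `S_y` are the filtered readings captured at the instants a
camera-side keypoint check certifies correct posture (head–neck line vertical
for `S_x`, shoulder line horizontal for `S_y`). Around them sit six
thresholds driving three hysteresis (Schmitt-trigger) comparators:

```
Href_x  = S_x − 0.01159·(b/150)     Lref_x  = S_x − 0.00854·(b/150)   (forward)
Href_yl = S_y + 0.02834·(d/150)     Lref_yl = S_y + 0.02441·(d/150)   (left)
Href_yr = S_y − 0.02834·(d/150)     Lref_yr = S_y − 0.02441·(d/150)   (right)
```

with `S_x` itself rescaled by slider `a/150` and `S_y` by `c/150`
(integer sliders in [1, 300], identity at 150). The trigger margins 0.01159 G
and 0.02834 G are the minimum forward and lateral tilt changes across a
packaged set of clinician-labeled measurements of three users — the
strictest standard the labels support. Each comparator trips when its
filtered input crosses the trigger threshold `Href` and releases only past
`Lref`; inside the band the output holds, which prevents chattering.
Active flags map to LEDs (middle = correct, top/left/right = tilt) and to
reminder messages such as `Too Forward & Left!!`, throttled to at most one
event per `10 s / warning_time`.

## Worked example

```python
import posturekit as pk
from posturekit.session_io import SessionConfig, run_session

# scripted wearer: 3 s upright (calibration), ramp to a 30 deg forward
# slouch, hold it, then straighten up
spec = pk.ManeuverSpec(segments=(
    pk.Segment(duration=3.0),
    pk.Segment(duration=2.0, target_pitch=30.0, transition="linear"),
    pk.Segment(duration=5.0, target_pitch=30.0),
    pk.Segment(duration=2.0, target_pitch=0.0, transition="linear"),
    pk.Segment(duration=3.0),
), noise_sigma=0.005, seed=3)

trace, _ = pk.simulate_trace(spec)
keypoints = pk.simulate_keypoints(
    pk.ManeuverSpec(segments=(pk.Segment(duration=3.0),), seed=3))

log = run_session(SessionConfig(duration=20.0, connected=True),
                  trace, keypoints)
for entry in log:
    print(entry)
```

prints

```
{'t': 0.9, 'type': 'calibration', 'status': 'complete', 'S_x': 1.0024948754846037, 'S_y': -0.0012791455995731487}
{'t': 4.0, 'type': 'state_change', 'flags': ['forward']}
{'t': 4.0, 'type': 'reminder', 'flags': ['forward'], 'message': 'Too Forward!!'}
{'t': 12.2, 'type': 'state_change', 'flags': []}
```

Calibration completes 0.9 s in (five-frame debounce per geometric check),
capturing this wearer's standards from the noisy filtered signal. One second
into the ramp the filtered A_x has fallen more than 0.01159 G below `S_x`,
so the forward comparator trips and a reminder fires; after the wearer
straightens, A_x climbs back past `Lref_x` and the flag clears at t = 12.2 s.

The same pipeline is available from a shell:

```
posturekit simulate --maneuver forward_tilt.yaml --seed 7 -o trace.csv --keypoints kp.csv
posturekit calibrate --trace trace.csv --keypoints kp.csv -o thresholds.json
posturekit assess trace.csv --thresholds thresholds.json -o events.jsonl
posturekit derive-offsets          # prints 0.01159 / 0.02834 from the packaged tables
```

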