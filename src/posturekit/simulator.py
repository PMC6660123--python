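"""Synthetic wearer: scripted orientation trajectories to sensor streams.

The necklace sits across the back of the neck with the accelerometer's x-axis
along the spine, y-axis lateral and z-axis anteroposterior.  A stationary
wearer's reading is the projection of gravity onto those axes: upright gives
(ax, ay, az) = (1, 0, 0) G; pitching forward lowers ax; rolling leftward
raises ay, rightward lowers it.  This convention is an assumption fixed from
the observed signal directions of the device (upright ax near 1 G, forward
tilt descending toward cos(pitch), leftward roll raising ay).

A :class:`ManeuverSpec` scripts pitch/roll targets over time; the simulator
interpolates the trajectory, projects gravity, and adds Gaussian sensor noise
plus an optional sinusoidal walking perturbation on ax.  Constant mounting-pitch and
mounting-roll parameters model a wearer whose neutral readings are offset
from the ideal (1, 0) G, as real fittings and body shapes show; they act on
the sensor side only and do not appear in the camera's keypoint view.  Matching keypoint streams expose the body's pitch in
side view (head-neck line) and roll in frontal view (shoulder line), enabling
hardware-free auto-calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import KeypointFrame
from .errors import ConfigurationError
from .signal_processing import AccelSample

#: Tilt angle (degrees) beyond which ground truth labels posture as poor.
DEFAULT_FLAG_ANGLE_DEG = 5.0

GROUND_TRUTH_COLUMNS = (
    "t_s", "pitch_deg", "roll_deg", "flag_forward", "flag_left", "flag_right"
)


def gravity_projection(pitch: float, roll: float) -> tuple[float, float, float]:
    """Project unit gravity onto the necklace axes for a pitch/roll posture.

    Parameters are in degrees, forward-positive pitch and left-positive roll,
    each within [-90, 90].  Returns (ax, ay, az) in G with
    ax = cos(pitch)·cos(roll), ay = sin(roll), az = -sin(pitch)·cos(roll);
    the squared components sum to one exactly.
    """
    if not (-90.0 <= pitch <= 90.0) or not (-90.0 <= roll <= 90.0):
        raise ConfigurationError(
            f"pitch/roll must lie in [-90, 90] degrees, got ({pitch}, {roll})"
        )
    p, r = math.radians(pitch), math.radians(roll)
    return (math.cos(p) * math.cos(r), math.sin(r), -math.sin(p) * math.cos(r))


@dataclass(frozen=True)
class Segment:
    """One scripted maneuver segment.

    ``transition='hold'`` jumps to the target orientation at the segment
    start; ``'linear'`` ramps from the current orientation across the
    segment's duration.
    """

    duration: float
    target_pitch: float = 0.0
    target_roll: float = 0.0
    transition: str = "hold"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError(f"segment duration must be positive, got {self.duration}")
        if abs(self.target_pitch) > 90 or abs(self.target_roll) > 90:
            raise ConfigurationError("|pitch| and |roll| must be <= 90 degrees")
        if self.transition not in ("hold", "linear"):
            raise ConfigurationError(f"unknown transition {self.transition!r}")


@dataclass(frozen=True)
class ManeuverSpec:
    """A scripted pitch/roll trajectory plus sensor noise model."""

    segments: tuple[Segment, ...]
    sample_rate: float = 10.0
    noise_sigma: float = 0.005
    walking: bool = False
    walking_amp: float = 0.05
    walking_freq: float = 2.0
    mounting_pitch: float = 0.0
    mounting_roll: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigurationError("maneuver needs at least one segment")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "ManeuverSpec":
        segs = tuple(Segment(**s) for s in d["segments"])
        kwargs = {k: v for k, v in d.items() if k != "segments"}
        return cls(segments=segs, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "ManeuverSpec":
        """Load a maneuver from YAML or JSON."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class GroundTruth:
    """Per-sample true orientation and posture flags for a simulated trace."""

    t: np.ndarray
    pitch_deg: np.ndarray
    roll_deg: np.ndarray
    flag_forward: np.ndarray
    flag_left: np.ndarray
    flag_right: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "pitch_deg": self.pitch_deg,
                "roll_deg": self.roll_deg,
                "flag_forward": self.flag_forward.astype(int),
                "flag_left": self.flag_left.astype(int),
                "flag_right": self.flag_right.astype(int),
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _trajectory(spec: ManeuverSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample times and interpolated body pitch/roll arrays for a maneuver."""
    total = sum(s.duration for s in spec.segments)
    n = int(round(total * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    pitch = np.empty(n)
    roll = np.empty(n)
    cur_p, cur_r = 0.0, 0.0
    seg_start = 0.0
    for seg in spec.segments:
        seg_end = seg_start + seg.duration
        mask = (t >= seg_start) & (t < seg_end)
        if seg.transition == "hold":
            pitch[mask] = seg.target_pitch
            roll[mask] = seg.target_roll
        else:  # linear ramp from current orientation across the segment
            frac = (t[mask] - seg_start) / seg.duration
            pitch[mask] = cur_p + frac * (seg.target_pitch - cur_p)
            roll[mask] = cur_r + frac * (seg.target_roll - cur_r)
        cur_p, cur_r = seg.target_pitch, seg.target_roll
        seg_start = seg_end
    return t, pitch, roll


def simulate_trace(
    spec: ManeuverSpec, flag_angle_deg: float = DEFAULT_FLAG_ANGLE_DEG
) -> tuple[list[AccelSample], GroundTruth]:
    """Turn a maneuver into an accelerometer trace with ground truth.

    Each reading is the gravity projection of the interpolated body angles
    (with the wearer's constant mounting roll added on the sensor side) plus
    i.i.d. Gaussian noise of ``noise_sigma`` per axis, plus — when walking is
    enabled — a sinusoid of ``walking_amp`` at ``walking_freq`` on ax.
    Deterministic for a given seed.  Ground-truth flags use the body angles:
    forward when pitch exceeds ``flag_angle_deg``, left/right likewise on
    roll.
    """
    t, pitch, roll = _trajectory(spec)
    proj = np.array(
        [
            gravity_projection(p + spec.mounting_pitch, r + spec.mounting_roll)
            for p, r in zip(pitch, roll)
        ]
    )
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        proj = proj + rng.normal(0.0, spec.noise_sigma, size=proj.shape)
    if spec.walking:
        proj[:, 0] += spec.walking_amp * np.sin(2 * np.pi * spec.walking_freq * t)
    samples = [
        AccelSample(t=float(tk), ax=float(a[0]), ay=float(a[1]), az=float(a[2]))
        for tk, a in zip(t, proj)
    ]
    truth = GroundTruth(
        t=t,
        pitch_deg=pitch,
        roll_deg=roll,
        flag_forward=pitch > flag_angle_deg,
        flag_left=roll > flag_angle_deg,
        flag_right=roll < -flag_angle_deg,
    )
    return samples, truth


@dataclass(frozen=True)
class BodyGeometry:
    """Body segment lengths (meters) used to place synthetic keypoints."""

    neck_height: float = 1.45
    neck_to_head: float = 0.25
    shoulder_halfwidth: float = 0.20

    def __post_init__(self) -> None:
        for name in ("neck_height", "neck_to_head", "shoulder_halfwidth"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def simulate_keypoints(
    spec: ManeuverSpec, geometry: BodyGeometry = BodyGeometry()
) -> list[KeypointFrame]:
    """Keypoint stream matching a maneuver's trace, one frame per sample.

    In side view the head-neck segment leans from vertical by the body pitch;
    in frontal view the shoulder line leans from horizontal by the body roll.
    The camera observes the body, so the sensor's mounting roll does not
    appear here.
    """
    t, pitch, roll = _trajectory(spec)
    frames = []
    for tk, p, r in zip(t, pitch, roll):
        pr, rr = math.radians(p), math.radians(r)
        neck = (0.0, geometry.neck_height)
        head = (
            neck[0] + geometry.neck_to_head * math.sin(pr),
            neck[1] + geometry.neck_to_head * math.cos(pr),
        )
        w = geometry.shoulder_halfwidth
        # left shoulder rises under a leftward (positive) roll
        left = (neck[0] - w * math.cos(rr), neck[1] - 0.05 + w * math.sin(rr))
        right = (neck[0] + w * math.cos(rr), neck[1] - 0.05 - w * math.sin(rr))
        frames.append(
            KeypointFrame(t=float(tk), head=head, neck=neck,
                          left_shoulder=left, right_shoulder=right)
        )
    return frames
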