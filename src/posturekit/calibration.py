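"""Producing and adjusting threshold sets.

Two calibration mechanisms feed :class:`~posturekit.posture_engine.ThresholdSet`:

* **Auto-calibration (primary).**  A camera-side keypoint stream marks the
  wearer's head, neck and shoulders.  When the head-neck line has been
  vertical for a debounce interval, the concurrent filtered A_x is frozen as
  the forward standard S_x; when the shoulder line has subsequently been
  horizontal, A_y is frozen as the lateral standard S_y.

* **Offset derivation.**  Clinician-labeled measurements give, per user and
  tilt direction, the standard value and the filtered reading at the point a
  posture was declared poor.  The minimum absolute change across users is the
  trigger offset — even the slightest labeled tilt tendency must alert.

* **Slider adjustment (secondary).**  Integer sliders a-d in [1, 300] rescale
  the standards (a, c) and the threshold offsets (b, d) by slider/150,
  relative to the stored calibration-time base values (non-compounding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    InsufficientDataError,
    TraceParseError,
)
from .posture_engine import SLIDER_CENTER, ThresholdSet, _check_slider
from .signal_processing import FilteredValue

#: Default angular tolerance (degrees) for the two geometric checks.
DEFAULT_TOL_DEG = 2.0

#: Consecutive qualifying frames required before a standard value is sampled.
DEFAULT_HOLD_FRAMES = 5

KEYPOINT_COLUMNS = (
    "t_s", "head_u", "head_v", "neck_u", "neck_v",
    "lsh_u", "lsh_v", "rsh_u", "rsh_v",
)

Point = tuple[float, float]


@dataclass(frozen=True)
class KeypointFrame:
    """One camera frame of 2-D skeletal keypoints in world coordinates.

    ``u`` is horizontal, ``v`` vertical with v increasing upward.  Depth
    coordinates, if present in source files, are ignored.
    """

    t: float
    head: Point
    neck: Point
    left_shoulder: Point
    right_shoulder: Point

    def __post_init__(self) -> None:
        for name in ("head", "neck", "left_shoulder", "right_shoulder"):
            p = getattr(self, name)
            if not (math.isfinite(p[0]) and math.isfinite(p[1])):
                raise ConfigurationError(f"keypoint {name} must be finite, got {p}")


@dataclass(frozen=True)
class LabeledMeasurement:
    """One clinician-labeled (user, direction, standard, poor-posture) record."""

    user: int
    direction: str  # forward | left | right
    standard: float
    measured: float

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "left", "right"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")

    @property
    def change(self) -> float:
        """Absolute tilt change |standard - measured| in G."""
        return abs(self.standard - self.measured)


def _angle_from_vertical_deg(a: Point, b: Point) -> float:
    du, dv = a[0] - b[0], a[1] - b[1]
    if du == 0.0 and dv == 0.0:
        raise DegenerateGeometryError(f"coincident points {a}")
    return math.degrees(math.atan2(abs(du), abs(dv)))


def is_vertical(head: Point, neck: Point, tol_deg: float = DEFAULT_TOL_DEG) -> bool:
    """True iff the head-neck segment is within ``tol_deg`` of vertical."""
    return _angle_from_vertical_deg(head, neck) <= tol_deg


def is_horizontal(
    left_shoulder: Point, right_shoulder: Point, tol_deg: float = DEFAULT_TOL_DEG
) -> bool:
    """True iff the shoulder segment is within ``tol_deg`` of horizontal.

    Symmetric in its arguments.
    """
    du, dv = left_shoulder[0] - right_shoulder[0], left_shoulder[1] - right_shoulder[1]
    if du == 0.0 and dv == 0.0:
        raise DegenerateGeometryError(f"coincident points {left_shoulder}")
    return math.degrees(math.atan2(abs(dv), abs(du))) <= tol_deg


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of keypoint auto-calibration.

    ``s_x``/``s_y`` are None for phases that never completed; ``s_x_time`` and
    ``s_y_time`` record the qualifying instants.
    """

    s_x: float | None = None
    s_y: float | None = None
    s_x_time: float | None = None
    s_y_time: float | None = None

    @property
    def complete(self) -> bool:
        return self.s_x is not None and self.s_y is not None

    @property
    def status(self) -> str:
        if self.complete:
            return "complete"
        if self.s_x is None:
            return "S_x not calibrated"
        return "S_y not calibrated"


def auto_calibrate(
    keypoints: Sequence[KeypointFrame],
    filtered: Sequence[FilteredValue],
    hold_frames: int = DEFAULT_HOLD_FRAMES,
    tol_deg: float = DEFAULT_TOL_DEG,
) -> CalibrationResult:
    """Set the standard values from keypoint-certified instants.

    Phase 1 (side profile): once :func:`is_vertical` has held for
    ``hold_frames`` consecutive frames, S_x is sampled from the filtered A_x
    nearest in time to the qualifying frame.  Phase 2 (frontal profile) then
    does the same for S_y via :func:`is_horizontal`.  Streams that end before
    both phases complete yield a partial result, not an exception.
    """
    if hold_frames < 1:
        raise ConfigurationError(f"hold_frames must be >= 1, got {hold_frames}")
    if not keypoints or not filtered:
        return CalibrationResult()
    ft = np.array([f.t for f in filtered])

    def nearest(t: float) -> FilteredValue:
        i = int(np.clip(np.searchsorted(ft, t), 0, len(ft) - 1))
        if i > 0 and abs(ft[i - 1] - t) <= abs(ft[i] - t):
            i -= 1
        return filtered[i]

    s_x = s_y = None
    s_x_t = s_y_t = None
    run = 0
    for frame in keypoints:
        if s_x is None:
            ok = is_vertical(frame.head, frame.neck, tol_deg)
        else:
            ok = is_horizontal(frame.left_shoulder, frame.right_shoulder, tol_deg)
        run = run + 1 if ok else 0
        if run >= hold_frames:
            fv = nearest(frame.t)
            if s_x is None:
                s_x, s_x_t = fv.A_x, frame.t
            else:
                s_y, s_y_t = fv.A_y, frame.t
                break
            run = 0
    return CalibrationResult(s_x=s_x, s_y=s_y, s_x_time=s_x_t, s_y_time=s_y_t)


def derive_offsets(
    measurements: Iterable[LabeledMeasurement],
) -> tuple[float, float]:
    """Trigger offsets (forward, lateral) as minima of labeled tilt changes.

    The forward offset is the minimum change over all forward measurements;
    the lateral offset is the minimum over both left and right measurements
    pooled.  Using the minimum makes the assessment strict: even the smallest
    labeled tilt tendency will trip the comparator.

    Raises
    ------
    InsufficientDataError
        If either the forward or the lateral direction has no measurements.
    """
    fwd = [m.change for m in measurements if m.direction == "forward"]
    lat = [m.change for m in measurements if m.direction in ("left", "right")]
    if not fwd or not lat:
        raise InsufficientDataError(
            "need at least one forward and one lateral (left/right) measurement"
        )
    return min(fwd), min(lat)


def build_threshold_set(
    s_x: float,
    s_y: float,
    offsets: tuple[float, float] | None = None,
    release_offsets: tuple[float, float] | None = None,
) -> ThresholdSet:
    """ThresholdSet from calibrated standards with sliders at center (150).

    By default the printed trigger/release constants are used; ``offsets``
    overrides the (forward, lateral) trigger margins and ``release_offsets``
    the corresponding release margins.
    """
    kwargs: dict = {"s_x_base": s_x, "s_y_base": s_y}
    if offsets is not None:
        kwargs["dh_fwd"], kwargs["dh_lat"] = offsets
    if release_offsets is not None:
        kwargs["dl_fwd"], kwargs["dl_lat"] = release_offsets
    return ThresholdSet(**kwargs)


def apply_sliders(base: ThresholdSet, a: int, b: int, c: int, d: int) -> ThresholdSet:
    """Manual fine adjustment: rescale standards and offsets by slider/150.

    Slider ``a`` scales S_x, ``b`` the forward offsets, ``c`` S_y, ``d`` the
    lateral offsets.  Scaling always applies to the stored calibration-time
    base values, never to previously adjusted ones, so applying the same
    sliders twice equals applying them once and (150, 150, 150, 150) is the
    identity.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        _check_slider(name, v)
    return replace(base, a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_measurements(path: str | Path) -> list[LabeledMeasurement]:
    """Read labeled measurements from CSV (``user,direction,standard_g,measured_g``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise TraceParseError(f"{path}: {exc}") from exc
    required = ["user", "direction", "standard_g", "measured_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing column(s) {missing} in header")
    return [
        LabeledMeasurement(
            user=int(r.user),
            direction=str(r.direction),
            standard=float(r.standard_g),
            measured=float(r.measured_g),
        )
        for r in df.itertuples()
    ]


def reference_measurements() -> list[LabeledMeasurement]:
    """The packaged clinician-labeled measurements of the three studied users."""
    with resources.as_file(
        resources.files("posturekit.data") / "orthopedist_tables.csv"
    ) as p:
        return read_measurements(p)


def read_keypoints(path: str | Path) -> list[KeypointFrame]:
    """Read a keypoint stream from keypoints-CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise TraceParseError(f"{path}: {exc}") from exc
    missing = [c for c in KEYPOINT_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing column(s) {missing} in header")
    return [
        KeypointFrame(
            t=float(r.t_s),
            head=(float(r.head_u), float(r.head_v)),
            neck=(float(r.neck_u), float(r.neck_v)),
            left_shoulder=(float(r.lsh_u), float(r.lsh_v)),
            right_shoulder=(float(r.rsh_u), float(r.rsh_v)),
        )
        for r in df.itertuples()
    ]


def write_keypoints(frames: Iterable[KeypointFrame], path: str | Path) -> None:
    """Write keypoint frames as keypoints-CSV."""
    rows = [
        (
            f.t, f.head[0], f.head[1], f.neck[0], f.neck[1],
            f.left_shoulder[0], f.left_shoulder[1],
            f.right_shoulder[0], f.right_shoulder[1],
        )
        for f in frames
    ]
    pd.DataFrame(rows, columns=list(KEYPOINT_COLUMNS)).to_csv(path, index=False)
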