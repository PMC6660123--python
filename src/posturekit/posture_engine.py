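"""Decision core of the necklace: hysteresis comparators and reminders.

Three two-threshold (Schmitt-trigger) comparators watch the filtered signals:
one on A_x for forward tilt and two on A_y for left and right tilt.  Each
comparator trips to 1 when its input crosses the trigger threshold ``href``
and releases to 0 only when the input crosses back past the release threshold
``lref``; inside the open band the output holds its value, which prevents
chattering near a single cutoff.

Thresholds are anchored on wearer-specific standard values S_x and S_y —
the filtered readings captured while posture is verified correct — offset by
empirically derived margins (see :mod:`posturekit.calibration`):

    Href_x  = S_x - 0.01159 * (b/150)      Lref_x  = S_x - 0.00854 * (b/150)
    Href_yl = S_y + 0.02834 * (d/150)      Lref_yl = S_y + 0.02441 * (d/150)
    Href_yr = S_y - 0.02834 * (d/150)      Lref_yr = S_y - 0.02441 * (d/150)

with S_x itself scaled by a/150 and S_y by c/150.  The four sliders a-d range
over [1, 300] with identity value 150 and act on the stored calibration-time
base values, so repeated adjustments never compound.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ConfigurationError, DegenerateBandError
from .signal_processing import FilteredValue

#: Forward trigger margin: minimum forward-tilt change over the labeled users (G).
FWD_TRIGGER_OFFSET = 0.01159
#: Forward release margin (G), selected to keep reminder cadence stable.
FWD_RELEASE_OFFSET = 0.00854
#: Lateral trigger margin: minimum left/right-tilt change over the labeled users (G).
LAT_TRIGGER_OFFSET = 0.02834
#: Lateral release margin (G).
LAT_RELEASE_OFFSET = 0.02441

SLIDER_MIN, SLIDER_CENTER, SLIDER_MAX = 1, 150, 300

#: Base reminder period in seconds; actual period is T0 / warning_time.
REMINDER_BASE_INTERVAL = 10.0

_MESSAGE_WORD = {"forward": "Forward", "left": "Left", "right": "Right"}
_FLAG_ORDER = ("forward", "left", "right")


def _check_slider(name: str, value: int) -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ConfigurationError(f"slider {name} must be an integer, got {value!r}")
    if not SLIDER_MIN <= value <= SLIDER_MAX:
        raise ConfigurationError(
            f"slider {name}={value} outside [{SLIDER_MIN}, {SLIDER_MAX}]"
        )
    return value


@dataclass(frozen=True)
class ThresholdSet:
    """Full threshold parameter block of the necklace.

    Stores the calibration-time base standards and the four offset constants;
    the standards S_x/S_y and the six comparator thresholds are derived
    properties so that slider adjustments are non-compounding by construction.
    """

    s_x_base: float
    s_y_base: float
    dh_fwd: float = FWD_TRIGGER_OFFSET
    dl_fwd: float = FWD_RELEASE_OFFSET
    dh_lat: float = LAT_TRIGGER_OFFSET
    dl_lat: float = LAT_RELEASE_OFFSET
    a: int = SLIDER_CENTER
    b: int = SLIDER_CENTER
    c: int = SLIDER_CENTER
    d: int = SLIDER_CENTER

    def __post_init__(self) -> None:
        for name in "abcd":
            _check_slider(name, getattr(self, name))
        for name in ("s_x_base", "s_y_base", "dh_fwd", "dl_fwd", "dh_lat", "dl_lat"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if not (0 < self.dl_fwd < self.dh_fwd):
            raise ConfigurationError(
                "forward offsets must satisfy 0 < release < trigger "
                f"(got release={self.dl_fwd}, trigger={self.dh_fwd})"
            )
        if not (0 < self.dl_lat < self.dh_lat):
            raise ConfigurationError(
                "lateral offsets must satisfy 0 < release < trigger "
                f"(got release={self.dl_lat}, trigger={self.dh_lat})"
            )

    # -- derived standards and thresholds ------------------------------------
    @property
    def S_x(self) -> float:
        return self.s_x_base * (self.a / SLIDER_CENTER)

    @property
    def S_y(self) -> float:
        return self.s_y_base * (self.c / SLIDER_CENTER)

    @property
    def Href_x(self) -> float:
        return self.S_x - self.dh_fwd * (self.b / SLIDER_CENTER)

    @property
    def Lref_x(self) -> float:
        return self.S_x - self.dl_fwd * (self.b / SLIDER_CENTER)

    @property
    def Href_yl(self) -> float:
        return self.S_y + self.dh_lat * (self.d / SLIDER_CENTER)

    @property
    def Lref_yl(self) -> float:
        return self.S_y + self.dl_lat * (self.d / SLIDER_CENTER)

    @property
    def Href_yr(self) -> float:
        return self.S_y - self.dh_lat * (self.d / SLIDER_CENTER)

    @property
    def Lref_yr(self) -> float:
        return self.S_y - self.dl_lat * (self.d / SLIDER_CENTER)

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "S_x": self.S_x, "S_y": self.S_y,
            "Href_x": self.Href_x, "Lref_x": self.Lref_x,
            "Href_yl": self.Href_yl, "Lref_yl": self.Lref_yl,
            "Href_yr": self.Href_yr, "Lref_yr": self.Lref_yr,
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        a, b, c, dd = (int(d.get(k, SLIDER_CENTER)) for k in "abcd")
        return cls(
            s_x_base=d["S_x"] / (a / SLIDER_CENTER),
            s_y_base=d["S_y"] / (c / SLIDER_CENTER),
            dh_fwd=(d["S_x"] - d["Href_x"]) / (b / SLIDER_CENTER),
            dl_fwd=(d["S_x"] - d["Lref_x"]) / (b / SLIDER_CENTER),
            dh_lat=(d["Href_yl"] - d["S_y"]) / (dd / SLIDER_CENTER),
            dl_lat=(d["Lref_yl"] - d["S_y"]) / (dd / SLIDER_CENTER),
            a=a, b=b, c=c, d=dd,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


class Polarity(enum.Enum):
    """Direction in which a comparator trips."""

    TRIGGERS_ABOVE = "triggers-above"  # out 0->1 when input rises past href
    TRIGGERS_BELOW = "triggers-below"  # out 0->1 when input falls past href


@dataclass(frozen=True)
class ComparatorState:
    """State of one hysteresis comparator (immutable; stepping returns a copy)."""

    href: float
    lref: float
    polarity: Polarity
    out: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.href) and math.isfinite(self.lref)):
            raise ConfigurationError("comparator thresholds must be finite")
        if self.href == self.lref:
            raise DegenerateBandError(
                f"href == lref == {self.href}: hysteresis band is degenerate"
            )


def comparator_step(state: ComparatorState, value: float) -> ComparatorState:
    """Advance a hysteresis comparator by one input value.

    For triggers-above polarity the output trips to 1 when the input exceeds
    ``href`` and releases to 0 when it drops below ``lref``; triggers-below is
    the mirror image.  Inside the band the output is retained.
    """
    if state.polarity is Polarity.TRIGGERS_ABOVE:
        if state.out == 0 and value > state.href:
            return replace(state, out=1)
        if state.out == 1 and value < state.lref:
            return replace(state, out=0)
    else:
        if state.out == 0 and value < state.href:
            return replace(state, out=1)
        if state.out == 1 and value > state.lref:
            return replace(state, out=0)
    return state


@dataclass(frozen=True)
class ComparatorBank:
    """The necklace's three comparators plus the lateral standard for tie-breaks."""

    forward: ComparatorState
    left: ComparatorState
    right: ComparatorState
    s_y: float


def build_comparators(th: ThresholdSet) -> ComparatorBank:
    """Instantiate the forward/left/right comparators from a ThresholdSet.

    Polarity follows the sign of ``href - lref``: the forward and right
    comparators trip when the signal falls (their trigger sits below the
    release), the left comparator when it rises.  All outputs start at 0 —
    posture is presumed correct immediately after calibration.
    """

    def _make(href: float, lref: float) -> ComparatorState:
        pol = Polarity.TRIGGERS_ABOVE if href > lref else Polarity.TRIGGERS_BELOW
        return ComparatorState(href=href, lref=lref, polarity=pol)

    return ComparatorBank(
        forward=_make(th.Href_x, th.Lref_x),
        left=_make(th.Href_yl, th.Lref_yl),
        right=_make(th.Href_yr, th.Lref_yr),
        s_y=th.S_y,
    )


def posture_message(flags: frozenset[str]) -> str | None:
    """Reminder text for a flag set, e.g. ``Too Forward & Left!!``; None if empty."""
    if not flags:
        return None
    parts = [_MESSAGE_WORD[f] for f in _FLAG_ORDER if f in flags]
    return "Too " + " & ".join(parts) + "!!"


@dataclass(frozen=True)
class PostureState:
    """Composite posture verdict: active tilt flags plus LED/message mapping."""

    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        unknown = self.flags - set(_FLAG_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown posture flags: {sorted(unknown)}")
        if {"left", "right"} <= self.flags:
            raise ConfigurationError("left and right flags are mutually exclusive")

    @property
    def led(self) -> frozenset[str]:
        """Active indicator LEDs; the middle LED alone means correct posture."""
        if not self.flags:
            return frozenset({"middle"})
        led = set()
        if "forward" in self.flags:
            led.add("top")
        if "left" in self.flags:
            led.add("left")
        if "right" in self.flags:
            led.add("right")
        return frozenset(led)

    @property
    def message(self) -> str | None:
        return posture_message(self.flags)


def assess(
    filtered: FilteredValue, bank: ComparatorBank
) -> tuple[ComparatorBank, PostureState]:
    """Feed one filtered value through the three comparators.

    A_x drives the forward comparator; A_y drives both lateral comparators.
    If both lateral comparators report poor posture at once (only possible
    transiently with pathological thresholds), the side whose trigger lies
    farther from the wearer's A_y reading is released: a physical tilt cannot
    be left and right simultaneously.
    """
    fwd = comparator_step(bank.forward, filtered.A_x)
    left = comparator_step(bank.left, filtered.A_y)
    right = comparator_step(bank.right, filtered.A_y)
    if left.out == 1 and right.out == 1:
        # keep the side toward which A_y actually deviates from the standard
        if filtered.A_y >= bank.s_y:
            right = replace(right, out=0)
        else:
            left = replace(left, out=0)
    flags = set()
    if fwd.out:
        flags.add("forward")
    if left.out:
        flags.add("left")
    if right.out:
        flags.add("right")
    new_bank = ComparatorBank(forward=fwd, left=left, right=right, s_y=bank.s_y)
    return new_bank, PostureState(flags=frozenset(flags))


@dataclass(frozen=True)
class ReminderEvent:
    """One poor-posture reminder sent from the necklace to the phone."""

    t: float
    flags: frozenset[str]
    message: str

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "type": "reminder",
            "flags": sorted(self.flags),
            "message": self.message,
        }


def emit_reminders(
    stream: Iterable[tuple[float, PostureState]],
    warning_time: int,
    base_interval: float = REMINDER_BASE_INTERVAL,
) -> list[ReminderEvent]:
    """Throttled reminder events for a time-ordered posture stream.

    A reminder fires when the flag set becomes non-empty (or changes while
    non-empty) and repeats while poor posture persists, no more often than
    once per ``base_interval / warning_time`` seconds.  No events are emitted
    while the flag set is empty.

    Raises
    ------
    ConfigurationError
        If ``warning_time`` < 1.
    """
    if warning_time < 1:
        raise ConfigurationError(f"warning_time must be >= 1, got {warning_time}")
    interval = base_interval / warning_time
    events: list[ReminderEvent] = []
    last_t: float | None = None
    last_flags: frozenset[str] = frozenset()
    for t, state in stream:
        if not state.flags:
            last_t, last_flags = None, frozenset()
            continue
        due = (
            last_t is None
            or state.flags != last_flags
            or t - last_t >= interval
        )
        if due:
            events.append(
                ReminderEvent(t=t, flags=state.flags, message=state.message or "")
            )
            last_t, last_flags = t, state.flags
    return events


def write_events(events: Iterable[ReminderEvent], path: str | Path) -> None:
    """Write reminder events as JSONL, one object per line."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict()) + "\n")
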