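"""Session orchestration: calibration phase, assessment loop, signal exchange.

A session mirrors the deployed system's workflow: the wearer is first
auto-calibrated from a keypoint stream (primary mechanism), timed setting
signals then fine-adjust sliders or toggle the phone connection (secondary
mechanism), and the assessment loop walks the filtered trace through the
comparators, emitting throttled reminders only while a phone is connected.
The original three-device TCP exchange is modeled as timed in-process signal
scripts speaking a one-line-per-signal text protocol; reminders are not
buffered while disconnected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .calibration import (
    KeypointFrame,
    apply_sliders,
    auto_calibrate,
    build_threshold_set,
)
from .errors import ConfigurationError, SignalParseError, UncalibratedSessionError
from .posture_engine import (
    REMINDER_BASE_INTERVAL,
    ComparatorBank,
    ThresholdSet,
    assess,
    build_comparators,
)
from .signal_processing import AccelSample, moving_average_filter

#: Signal kinds and the type of the value they carry (None = no value).
SIGNAL_KINDS: dict[str, type | None] = {
    "calibrate_S_x": float,
    "calibrate_S_y": float,
    "set_warning_time": int,
    "set_FW_center": int,
    "set_FW_limit": int,
    "set_LR_center": int,
    "set_LR_limit": int,
    "connect": None,
    "disconnect": None,
}

_SLIDER_KINDS = {"set_FW_center", "set_FW_limit", "set_LR_center", "set_LR_limit"}


@dataclass(frozen=True)
class SettingSignal:
    """One parameter-update or connection signal sent to the necklace."""

    kind: str
    value: float | int | None = None

    def __post_init__(self) -> None:
        if self.kind not in SIGNAL_KINDS:
            raise ConfigurationError(f"unknown signal kind {self.kind!r}")
        vtype = SIGNAL_KINDS[self.kind]
        if vtype is None:
            if self.value is not None:
                raise ConfigurationError(f"signal {self.kind} carries no value")
            return
        if self.value is None:
            raise ConfigurationError(f"signal {self.kind} requires a value")
        if self.kind in _SLIDER_KINDS and not 1 <= int(self.value) <= 300:
            raise ConfigurationError(
                f"slider signal {self.kind} value {self.value} outside [1, 300]"
            )
        if self.kind == "set_warning_time" and int(self.value) < 1:
            raise ConfigurationError("set_warning_time value must be >= 1")


def encode_signal(signal: SettingSignal) -> str:
    """Encode a signal as one line of text, e.g. ``set_FW_center 200``."""
    if signal.value is None:
        return signal.kind
    return f"{signal.kind} {signal.value}"


def decode_signal(line: str) -> SettingSignal:
    """Decode one protocol line back into a :class:`SettingSignal`.

    Raises :class:`~posturekit.errors.SignalParseError` on malformed lines or
    unknown kinds.
    """
    parts = line.strip().split()
    if not parts:
        raise SignalParseError("empty signal line")
    kind = parts[0]
    if kind not in SIGNAL_KINDS:
        raise SignalParseError(f"unknown signal kind {kind!r}")
    vtype = SIGNAL_KINDS[kind]
    if vtype is None:
        if len(parts) != 1:
            raise SignalParseError(f"signal {kind} carries no value: {line!r}")
        return SettingSignal(kind=kind)
    if len(parts) != 2:
        raise SignalParseError(f"signal {kind} requires exactly one value: {line!r}")
    try:
        value = vtype(parts[1])
    except ValueError as exc:
        raise SignalParseError(f"bad value in signal line {line!r}") from exc
    return SettingSignal(kind=kind, value=value)


@dataclass
class SessionConfig:
    """Operating parameters of one monitoring session."""

    duration: float = 8 * 3600.0  # set operating time, seconds
    sample_rate: float = 10.0
    warning_time: int = 1
    connected: bool = False
    thresholds: ThresholdSet | None = None  # preloaded instead of auto-calibration
    reminder_base_interval: float = REMINDER_BASE_INTERVAL
    filter_window: int = 10

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.warning_time < 1:
            raise ConfigurationError("warning_time must be >= 1")


def _copy_outs(new: ComparatorBank, old: ComparatorBank) -> ComparatorBank:
    """Carry comparator outputs across a threshold update."""
    return ComparatorBank(
        forward=replace(new.forward, out=old.forward.out),
        left=replace(new.left, out=old.left.out),
        right=replace(new.right, out=old.right.out),
        s_y=new.s_y,
    )


def run_session(
    config: SessionConfig,
    trace: Sequence[AccelSample],
    keypoints: Sequence[KeypointFrame] = (),
    signals: Sequence[tuple[float, SettingSignal]] = (),
) -> list[dict]:
    """Execute a full session and return its append-only, time-ordered log.

    Phases run in workflow order: keypoint auto-calibration (when a keypoint
    stream is given), then the assessment loop over the filtered trace, with
    scripted signals applied at their timestamps.  Reminders obey the
    ``reminder_base_interval / warning_time`` throttle and are only logged
    while connected.  The loop stops at ``config.duration``.

    Raises
    ------
    UncalibratedSessionError
        If neither auto-calibration completes nor preloaded thresholds exist.
    """
    filtered = moving_average_filter(trace, config.filter_window)
    log: list[dict] = []
    assess_from = 0.0

    th = config.thresholds
    if keypoints:
        calib = auto_calibrate(keypoints, filtered)
        entry_t = calib.s_y_time if calib.complete else (keypoints[-1].t)
        log.append(
            {
                "t": float(entry_t),
                "type": "calibration",
                "status": calib.status,
                "S_x": calib.s_x,
                "S_y": calib.s_y,
            }
        )
        if calib.complete:
            th = build_threshold_set(calib.s_x, calib.s_y)
            assess_from = float(calib.s_y_time)
    if th is None:
        raise UncalibratedSessionError(
            "assessment requires completed auto-calibration or preloaded thresholds"
        )

    bank = build_comparators(th)
    warning_time = config.warning_time
    connected = config.connected
    queue = sorted(signals, key=lambda p: p[0])
    qi = 0
    last_emit_t: float | None = None
    last_emit_flags: frozenset[str] = frozenset()
    prev_flags: frozenset[str] = frozenset()

    for fv in filtered:
        if fv.t > config.duration:
            break
        # apply all scripted signals due at or before this sample
        while qi < len(queue) and queue[qi][0] <= fv.t:
            sig_t, sig = queue[qi]
            qi += 1
            entry = {"t": float(sig_t), "type": "setting", "kind": sig.kind,
                     "value": sig.value}
            if sig.kind == "connect":
                connected = True
            elif sig.kind == "disconnect":
                connected = False
            elif sig.kind == "set_warning_time":
                warning_time = int(sig.value)
            else:
                if sig.kind == "calibrate_S_x":
                    th = replace(th, s_x_base=float(sig.value))
                elif sig.kind == "calibrate_S_y":
                    th = replace(th, s_y_base=float(sig.value))
                elif sig.kind == "set_FW_center":
                    th = apply_sliders(th, int(sig.value), th.b, th.c, th.d)
                elif sig.kind == "set_FW_limit":
                    th = apply_sliders(th, th.a, int(sig.value), th.c, th.d)
                elif sig.kind == "set_LR_center":
                    th = apply_sliders(th, th.a, th.b, int(sig.value), th.d)
                elif sig.kind == "set_LR_limit":
                    th = apply_sliders(th, th.a, th.b, th.c, int(sig.value))
                bank = _copy_outs(build_comparators(th), bank)
                entry["thresholds"] = th.to_dict()
            log.append(entry)

        if fv.t < assess_from:
            continue
        bank, state = assess(fv, bank)
        if state.flags != prev_flags:
            log.append(
                {"t": fv.t, "type": "state_change", "flags": sorted(state.flags)}
            )
            prev_flags = state.flags
        if not state.flags:
            last_emit_t, last_emit_flags = None, frozenset()
            continue
        if not connected:
            continue
        interval = config.reminder_base_interval / warning_time
        due = (
            last_emit_t is None
            or state.flags != last_emit_flags
            or fv.t - last_emit_t >= interval
        )
        if due:
            log.append(
                {
                    "t": fv.t,
                    "type": "reminder",
                    "flags": sorted(state.flags),
                    "message": state.message,
                }
            )
            last_emit_t, last_emit_flags = fv.t, state.flags
    return log


def write_log(entries: Iterable[dict], path: str | Path) -> None:
    """Write a session log as JSONL, one entry per line."""
    with open(path, "w") as fh:
        for entry in entries:
            fh.write(json.dumps(entry) + "\n")


def read_signal_script(path: str | Path) -> list[tuple[float, SettingSignal]]:
    """Read a timed signal script: lines of ``<t_seconds> <signal line>``.

    Blank lines and ``#`` comments are ignored; a malformed line raises
    :class:`~posturekit.errors.SignalParseError` naming the line number.
    """
    script: list[tuple[float, SettingSignal]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            t_str, _, rest = line.partition(" ")
            script.append((float(t_str), decode_signal(rest)))
        except (ValueError, SignalParseError) as exc:
            raise SignalParseError(f"line {lineno}: {exc}") from exc
    return script
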