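"""Acquisition and digital filtering of triaxial accelerometer samples.

The necklace's accelerometer is read at a fixed rate (10 Hz by default) and
each axis reports the projection of gravity in G.  Assessment never consumes
raw readings directly: every axis is smoothed with a trailing moving average
over the current reading and the previous ``window - 1`` readings, which
suppresses motion noise (walking) while preserving slow postural tilt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyTraceError, NonMonotonicTimeError, TraceParseError

#: Default moving-average window: the current reading plus the previous nine.
DEFAULT_WINDOW = 10

#: Default sampling period in seconds.
DEFAULT_SAMPLE_PERIOD = 0.1

#: Accelerometer full-scale guard in G.
FULL_SCALE_G = 4.0

TRACE_COLUMNS = ("t_s", "ax_g", "ay_g", "az_g")


@dataclass(frozen=True)
class AccelSample:
    """One timestamped raw triaxial gravitational-acceleration reading.

    Attributes
    ----------
    t : float
        Seconds since session start.
    ax : float
        G along the spine axis (reads ~1 G when the wearer stands upright).
    ay : float
        G along the lateral axis (positive for a leftward tilt).
    az : float
        G along the anteroposterior axis; carried through but unused by
        posture assessment.
    """

    t: float
    ax: float
    ay: float
    az: float = 0.0


@dataclass(frozen=True)
class FilteredValue:
    """One digitally filtered reading A_x/A_y aligned with a raw sample.

    ``window_fill`` counts how many raw samples actually contributed to the
    average; it is smaller than the nominal window during warm-up.
    """

    t: float
    A_x: float
    A_y: float
    window_fill: int


def _as_arrays(samples: Sequence[AccelSample]) -> tuple[np.ndarray, ...]:
    t = np.array([s.t for s in samples], dtype=float)
    ax = np.array([s.ax for s in samples], dtype=float)
    ay = np.array([s.ay for s in samples], dtype=float)
    az = np.array([s.az for s in samples], dtype=float)
    return t, ax, ay, az


def moving_average_filter(
    samples: Sequence[AccelSample], window: int = DEFAULT_WINDOW
) -> list[FilteredValue]:
    """Trailing moving average of a trace, one filtered value per raw sample.

    Element ``k`` of the output is the arithmetic mean of raw elements
    ``max(0, k - window + 1) .. k`` on each of the x and y axes.  During
    warm-up (before ``window`` samples exist) all available samples are
    averaged, so output and input stay index-aligned from the first reading.

    Parameters
    ----------
    samples : sequence of AccelSample
        Non-empty, with strictly increasing timestamps.
    window : int
        Positive window length; 10 by default.

    Raises
    ------
    EmptyTraceError
        If ``samples`` is empty.
    NonMonotonicTimeError
        If timestamps are not strictly increasing.
    ValueError
        If ``window`` is not positive.
    """
    if window < 1:
        raise ValueError(f"window must be a positive count, got {window}")
    samples = list(samples)
    if not samples:
        raise EmptyTraceError("cannot filter an empty trace")
    t, ax, ay, _ = _as_arrays(samples)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise NonMonotonicTimeError(
            f"timestamps must be strictly increasing (violated at sample {bad})"
        )
    fa_x = pd.Series(ax).rolling(window, min_periods=1).mean().to_numpy()
    fa_y = pd.Series(ay).rolling(window, min_periods=1).mean().to_numpy()
    fill = np.minimum(np.arange(len(t)) + 1, window)
    return [
        FilteredValue(t=float(t[k]), A_x=float(fa_x[k]), A_y=float(fa_y[k]),
                      window_fill=int(fill[k]))
        for k in range(len(t))
    ]


def read_trace(path: str | Path, full_scale: float = FULL_SCALE_G) -> list[AccelSample]:
    """Read an accelerometer trace from trace-CSV.

    The dialect is ``t_s,ax_g,ay_g,az_g`` with one sample per row; the
    ``az_g`` column is optional on input (zero-filled when absent).

    Raises
    ------
    TraceParseError
        On a missing required column or a non-numeric cell; the message names
        the offending line.
    NonMonotonicTimeError
        If timestamps are not strictly increasing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV structure
        raise TraceParseError(f"{path}: {exc}") from exc
    required = ["t_s", "ax_g", "ay_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing column(s) {missing} in header")
    if "az_g" not in df.columns:
        df = df.assign(az_g=0.0)
    for col in TRACE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: one for the header row, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise TraceParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    for col in ("ax_g", "ay_g", "az_g"):
        if (df[col].abs() > full_scale).any():
            line = int(df.index[df[col].abs() > full_scale][0]) + 2
            raise TraceParseError(
                f"{path}: |{col}| exceeds full scale {full_scale} G at line {line}"
            )
    t = df["t_s"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise NonMonotonicTimeError(f"{path}: timestamps must be strictly increasing")
    return [
        AccelSample(t=float(r.t_s), ax=float(r.ax_g), ay=float(r.ay_g), az=float(r.az_g))
        for r in df.itertuples()
    ]


def write_trace(samples: Iterable[AccelSample], path: str | Path) -> None:
    """Write samples as trace-CSV (lossless round trip with :func:`read_trace`)."""
    df = pd.DataFrame(
        [(s.t, s.ax, s.ay, s.az) for s in samples], columns=list(TRACE_COLUMNS)
    )
    df.to_csv(path, index=False)


def write_filtered(values: Iterable[FilteredValue], path: str | Path) -> None:
    """Write filtered values as CSV with header ``t_s,Ax_g,Ay_g,window_fill``."""
    df = pd.DataFrame(
        [(v.t, v.A_x, v.A_y, v.window_fill) for v in values],
        columns=["t_s", "Ax_g", "Ay_g", "window_fill"],
    )
    df.to_csv(path, index=False)
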