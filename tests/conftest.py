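import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import posturekit as pk

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def upright_spec():
    """Three seconds of a still, ideally mounted wearer at 10 Hz."""
    return pk.ManeuverSpec(segments=(pk.Segment(duration=3.0),), seed=11)


@pytest.fixture
def default_thresholds():
    """Threshold set for an ideal wearer (S_x=1, S_y=0, sliders centered)."""
    return pk.build_threshold_set(1.0, 0.0)


def make_trace(values_x, values_y=None, dt=0.1):
    """Build an AccelSample list from explicit per-axis values."""
    values_y = values_y if values_y is not None else [0.0] * len(values_x)
    return [
        pk.AccelSample(t=k * dt, ax=float(x), ay=float(y))
        for k, (x, y) in enumerate(zip(values_x, values_y))
    ]


def tilt_session_spec(seed, pitch=30.0):
    """Calibrate-upright, tilt-forward, straighten maneuver used in several tests."""
    return pk.ManeuverSpec(
        segments=(
            pk.Segment(duration=3.0),
            pk.Segment(duration=2.0, target_pitch=pitch, transition="linear"),
            pk.Segment(duration=5.0, target_pitch=pitch),
            pk.Segment(duration=2.0, target_pitch=0.0, transition="linear"),
            pk.Segment(duration=3.0),
        ),
        noise_sigma=0.005,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
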