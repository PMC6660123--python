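"""Exception hierarchy shared by all posturekit modules."""


class PostureKitError(Exception):
    """Base class for all posturekit errors."""


class EmptyTraceError(PostureKitError):
    """An operation received an empty accelerometer trace."""


class NonMonotonicTimeError(PostureKitError):
    """Timestamps in a trace are not strictly increasing."""


class TraceParseError(PostureKitError):
    """A trace or keypoint CSV file is malformed."""


class DegenerateBandError(PostureKitError):
    """A hysteresis comparator was configured with href == lref."""


class ConfigurationError(PostureKitError):
    """A parameter is outside its valid range or violates an invariant."""


class DegenerateGeometryError(PostureKitError):
    """A geometric check received coincident keypoints."""


class InsufficientDataError(PostureKitError):
    """Labeled measurements do not cover every required tilt direction."""


class UncalibratedSessionError(PostureKitError):
    """Posture assessment was requested before any standard values existed."""


class SignalParseError(PostureKitError):
    """A setting-signal line could not be decoded."""
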