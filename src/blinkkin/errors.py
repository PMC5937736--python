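"""Exception hierarchy for the blinkkin pipeline.

Every error raised by the package derives from :class:`BlinkKinError`, so
callers can catch pipeline problems without masking programming errors.
"""


class BlinkKinError(Exception):
    """Base class for all blinkkin errors."""


class InvalidInputError(BlinkKinError):
    """Input data violates a structural precondition (shape, bounds, sampling)."""


class InvalidParameterError(BlinkKinError):
    """A user-supplied parameter is outside its valid domain."""


class DegenerateCurveError(BlinkKinError):
    """A curve is constant where normalization by its extremum is required."""


class MalformedBlinkError(BlinkKinError):
    """A segment does not exhibit the canonical blink landmark structure."""


class InvalidIntervalError(BlinkKinError):
    """An integration interval contains no samples or is reversed."""


class InfeasibleUniquenessError(BlinkKinError):
    """More unique bootstrap subsets requested than combinatorially exist."""


class PlacementError(BlinkKinError):
    """Requested blink density cannot fit into the trace duration."""


class InvalidProfileError(BlinkKinError):
    """A synthetic subject profile has degenerate or out-of-range parameters."""


class ConfigError(BlinkKinError):
    """Pipeline configuration is missing a key or holds an invalid value."""
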