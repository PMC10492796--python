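"""Exception hierarchy.

Every error raised by this package derives from :class:`CardioKymoError`,
so callers can distinguish pipeline failures from programming errors.
"""


class CardioKymoError(Exception):
    """Base class for all cardiokymo errors."""


class ParameterError(CardioKymoError, ValueError):
    """A parameter violates a documented invariant (the message names it)."""


class GeometryError(CardioKymoError):
    """A simulated cell does not fit on the scan line."""


class DegenerateInputError(CardioKymoError):
    """Input carries no usable signal (constant image, empty stack, ...)."""


class SegmentationError(CardioKymoError):
    """Cell-edge segmentation failed; carries the offending line index."""

    def __init__(self, message: str, line_index: int | None = None):
        super().__init__(message)
        self.line_index = line_index


class NoResponseError(CardioKymoError):
    """No beat in the record produced a measurable contraction."""


class NoTransientError(CardioKymoError):
    """No beat in the record produced a measurable Ca2+ transient."""


class BaselineError(CardioKymoError):
    """The pre-stimulus baseline window is empty or unusable."""


class MissingEventError(CardioKymoError, KeyError):
    """A required respirometry titration event is absent from the trace."""

    def __init__(self, event: str):
        super().__init__(f"required respirometry event missing: {event!r}")
        self.event = event


class ConfigurationError(CardioKymoError):
    """A run configuration is inconsistent (missing reference, bad design)."""
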