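"""Exception hierarchy for the iPPG pipeline.

Each pipeline stage raises a subclass of :class:`IppgError`, so callers
(and the CLI exit-code mapping) can distinguish configuration problems,
unreadable inputs, and signals too poor to yield a heart rate.
"""


class IppgError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(IppgError):
    """A parameter combination is invalid (e.g. window larger than frame)."""


class InputError(IppgError):
    """The input could not be read or fails the sampling requirements."""


class ValidationError(InputError):
    """The video violates the minimum fps / duration requirements."""


class SignalQualityError(IppgError):
    """The extracted signal is too degenerate to measure a heart rate."""


class DegenerateSignalError(SignalQualityError):
    """A trace has no usable variation (all-zero channel, zero-std chrominance)."""


class InsufficientSignalError(SignalQualityError):
    """Fewer than two beats could be located in the pulse signal."""


class DegenerateFlowError(SignalQualityError):
    """The LK normal matrix is near-singular (aperture problem)."""


class TrackingError(SignalQualityError):
    """Point tracking collapsed before half of the sequence."""
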