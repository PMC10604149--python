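"""Exception hierarchy shared across the package."""


class CuttleflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CuttleflowError, ValueError):
    """A physical or numerical parameter violates its contract."""


class InvalidInputError(CuttleflowError, ValueError):
    """An input object (trace, series, grid) violates its contract."""


class EmptyInputError(InvalidInputError):
    """An operation that requires data received an empty input."""


class FormatError(CuttleflowError, ValueError):
    """A file does not conform to the expected on-disk format.

    The message names the offending line or column where possible.
    """


class NumericalFailureError(CuttleflowError, RuntimeError):
    """An integrator or solver failed; carries the last valid state."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class StepInstabilityError(NumericalFailureError):
    """Explicit time stepping produced an unphysical overshoot."""


class TrackingFailureError(CuttleflowError, RuntimeError):
    """Front tracking failed on too large a fraction of frames."""
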