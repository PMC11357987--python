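"""Exception hierarchy shared across the package."""


class NeurosysidError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NeurosysidError, ValueError):
    """A parameter is outside its documented domain."""


class InsufficientSamplesError(NeurosysidError, ValueError):
    """The data segment is too short for the requested operation."""


class DegenerateSignalError(NeurosysidError, ValueError):
    """The signal is degenerate for the operation (e.g. zero variance)."""


class NumericalDegeneracyError(NeurosysidError, RuntimeError):
    """A numerical routine failed past its fallback tolerances."""


class IntegrationFailureError(NeurosysidError, RuntimeError):
    """A simulated state became non-finite (blow-up)."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class FormatError(NeurosysidError, ValueError):
    """A data file violates the expected on-disk format."""


class TrainingFailureError(NeurosysidError, RuntimeError):
    """Model training produced a non-finite loss."""
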