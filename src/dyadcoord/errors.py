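"""Exception hierarchy for the dyadcoord pipeline.

Every error raised by the package derives from :class:`DyadCoordError` so
batch drivers can distinguish pipeline failures from programming errors.
"""


class DyadCoordError(Exception):
    """Base class for all dyadcoord errors."""


class FormatError(DyadCoordError):
    """A file does not conform to the expected CSV dialect."""


class EmptyInputError(DyadCoordError):
    """An input series or matrix is empty or too small to be meaningful."""


class ValidationError(DyadCoordError):
    """An input violates a domain-type invariant (non-finite, bad range...)."""


class TooShortError(DyadCoordError):
    """A series is too short for the requested operation."""


class ConfigError(DyadCoordError):
    """A configuration value is out of its admissible range."""


class DegenerateSignalError(DyadCoordError):
    """A signal is constant or all-zero where structure is required."""


class AlignmentError(DyadCoordError):
    """Two series that must be aligned have incompatible shapes."""


class TuningError(DyadCoordError):
    """The radius tuner could not reach the target recurrence rate."""

    def __init__(self, message: str, closest_rate: float | None = None):
        super().__init__(message)
        self.closest_rate = closest_rate


class ImputationError(DyadCoordError):
    """A respondent has no observed items in a subscale to impute from."""


class ModelSpecError(DyadCoordError):
    """A model specification references missing columns or illegal terms."""


class FitError(DyadCoordError):
    """The mixed-model optimiser failed to converge."""


class IntegrationError(DyadCoordError):
    """The stochastic phase integrator took an unstable step."""


class UndefinedProportionError(DyadCoordError):
    """A gaze proportion is undefined because every sample is missing."""
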