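"""Exception hierarchy for the screening pipeline.

Every error raised on a user-facing path derives from :class:`TimsScreenError`
so that the CLI can map error families onto distinct exit codes.
"""


class TimsScreenError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class InvalidInputError(TimsScreenError, ValueError):
    """A scalar or array argument violates a precondition."""

    exit_code = 3


class ConfigValidationError(TimsScreenError, ValueError):
    """A scenario or run configuration is invalid.

    Carries the full list of violations so a user can fix them in one pass.
    """

    exit_code = 2

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration: " + "; ".join(self.violations))


class InsufficientCalibrantsError(InvalidInputError):
    """Fewer than two calibrant ions were supplied."""


class SingularFitError(TimsScreenError):
    """The calibration design matrix is degenerate (identical predictors)."""

    exit_code = 4


class UncalibratedDataError(TimsScreenError):
    """An operation needing a CCS calibration was called without one."""

    exit_code = 4


class InsufficientLevelsError(InvalidInputError):
    """Too few concentration levels for a dilution-series operation."""


class PolarityMismatchError(TimsScreenError):
    """Library polarity does not match the peak cloud's ionization mode."""

    exit_code = 4


class InvalidStateError(TimsScreenError):
    """An operation was called on an annotation in an incompatible category."""

    exit_code = 4


class IOFormatError(TimsScreenError):
    """A file did not conform to one of the documented text formats."""

    exit_code = 5
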