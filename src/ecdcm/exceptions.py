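"""Exception hierarchy.

Exit-code mapping used by the command line interface:
``ConfigError`` -> 2, ``DataError`` -> 3, ``NumericalError`` -> 4.
"""


class EcdcmError(Exception):
    """Base class for all package errors."""


class ArgumentError(EcdcmError, ValueError):
    """An argument violates a documented precondition."""


class StabilityError(EcdcmError):
    """A coupling matrix has an eigenvalue with non-negative real part."""


class IntegrationError(EcdcmError):
    """Numerical integration diverged (non-finite state)."""


class NumericalError(EcdcmError):
    """A numerical operation failed (singular system, NaN gradient, ...)."""


class DataError(EcdcmError):
    """Input data violate a requirement (too short, degenerate, ...)."""


class ConfigError(EcdcmError):
    """Invalid run or model configuration."""


class ROIError(EcdcmError):
    """A region of interest cannot be applied to an image."""


class ManifestError(DataError):
    """A cohort manifest failed validation.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
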