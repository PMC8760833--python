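"""Exception hierarchy shared across the package."""


class CocultRsmError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(CocultRsmError):
    """The requested experimental design is structurally impossible."""


class InvalidParameterError(CocultRsmError, ValueError):
    """A numeric parameter is outside its valid domain."""


class DimensionError(CocultRsmError, ValueError):
    """Vector / factor-count mismatch between two objects."""


class ParseError(CocultRsmError):
    """A delimited-text artifact could not be parsed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(CocultRsmError):
    """A parsed or constructed object violates a structural invariant."""


class UnsupportedDegreeError(CocultRsmError):
    """Polynomial degree beyond the supported cubic scope."""


class SingularDesignError(CocultRsmError):
    """The model matrix is rank deficient for the chosen terms."""


class EmptyPoolError(CocultRsmError):
    """A selection routine was given no candidate terms."""


class DegenerateAnovaError(CocultRsmError):
    """ANOVA is undefined (e.g. zero residual degrees of freedom)."""


class LeverageError(CocultRsmError):
    """A leave-one-out quantity is undefined because a leverage equals 1."""


class DegenerateGoalError(CocultRsmError, ValueError):
    """A desirability goal with y_max == y_min has no valid transform."""


class NumericError(CocultRsmError):
    """A numeric routine produced non-finite values."""


class ConfigurationError(CocultRsmError):
    """An operation was configured inconsistently (e.g. wrong free-factor count)."""


class ConversionError(CocultRsmError):
    """A calibration-based unit conversion is impossible (non-invertible curve)."""
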