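"""Exception hierarchy for cpmap.

All package-specific failures derive from :class:`CPMError` so callers can
catch one base class at the CLI boundary.
"""


class CPMError(Exception):
    """Base class for all cpmap errors."""


class SchemaError(CPMError):
    """A table or parameter file does not match the active covariate schema."""


class RowError(CPMError):
    """A single data row could not be parsed.

    Carries the 1-based line number of the offending row (header = line 1).
    """

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class EncodingError(CPMError):
    """A covariate value is not a known level of its categorical variable."""


class DegenerateScaleError(CPMError):
    """Coordinate scaling is impossible (zero variance on an axis)."""


class ParameterDomainError(CPMError):
    """Model parameters outside their admissible domain (sigma <= 0, |rho| >= 1,
    non-positive-definite correlation matrix, non-increasing thresholds...)."""


class EstimationError(CPMError):
    """Estimation cannot proceed (missing mode, unobserved class, rank-deficient
    design)."""


class ConfigurationError(CPMError):
    """Inconsistent configuration (e.g. profile schema does not match the model
    schemas when building a raster)."""
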