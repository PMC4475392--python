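"""Exception hierarchy shared across the package."""


class SoilscapeError(Exception):
    """Base class for all package errors."""


class ValidationError(SoilscapeError, ValueError):
    """Invalid parameter or malformed input value."""


class DegenerateDataError(SoilscapeError, ValueError):
    """Input carries no usable information (e.g. all values identical)."""


class GeometryError(SoilscapeError, ValueError):
    """Sampling geometry cannot satisfy the request."""


class DecompositionError(SoilscapeError, ValueError):
    """A covariance/correlation matrix is not positive definite."""


class ConfigurationError(SoilscapeError, ValueError):
    """Inconsistent or unsatisfiable configuration."""


class SchemaError(SoilscapeError, KeyError):
    """Referenced columns or names are missing from a table."""


class FittingError(SoilscapeError, RuntimeError):
    """Model fitting failed to converge."""


class FormatError(SoilscapeError, ValueError):
    """On-disk artifact violates the documented dialect."""
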