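"""Exception hierarchy shared across the package."""


class LakemoxError(Exception):
    """Base class for all package-specific errors."""


class OutOfDomainError(LakemoxError, ValueError):
    """Input outside the physically supported range of a parameterization."""


class InvalidDataError(LakemoxError, ValueError):
    """Data violate a precondition (nonpositive concentration, bad grid, ...)."""


class InsufficientDataError(InvalidDataError):
    """Too few observations to fit or summarize."""


class DegenerateLakeError(InvalidDataError):
    """Lake geometry too shallow/small for the requested grid."""


class UndefinedRatioError(LakemoxError, ArithmeticError):
    """CH4:O2 ratio requested at zero O2 — the water is anoxic, not a numeric bug.

    Callers catching this should treat the depth as anoxic rather than abort.
    """


class IdentifiabilityError(LakemoxError, ValueError):
    """A model coefficient cannot be estimated from a degenerate design."""


class ExtrapolationError(LakemoxError, ValueError):
    """Requested grid extends beyond the tabulated hypsography."""


class ConfigurationError(LakemoxError, ValueError):
    """A required configuration entry (e.g. a layer rate) is missing."""
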