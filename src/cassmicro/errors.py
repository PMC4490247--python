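"""Exception hierarchy shared across the package."""


class CassError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CassError, ValueError):
    """A value violates a documented precondition (negative ionic strength, empty profile, ...)."""


class ConfigurationError(CassError, ValueError):
    """A configuration is incomplete or inconsistent (missing K, unknown rank, infeasible fractions)."""


class UndefinedQuotientError(CassError, ArithmeticError):
    """A reaction quotient involves a zero activity and no detection-limit floor is configured."""


class UndefinedFitError(CassError, ArithmeticError):
    """A regression cannot be fitted (zero variance in the predictor)."""
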