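"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument is outside the physical/mathematical domain of an operation."""


class UndefinedRatioError(DomainError):
    """A ratio (e.g. the tail ratio xi) is undefined for the given amplitudes."""


class ConfigurationError(ValueError):
    """A run configuration violates a documented precondition (step size, quadrature order, ...)."""


class ConvergenceError(RuntimeError):
    """A truncated expansion cannot reach the requested tolerance."""


class InsufficientDataError(ValueError):
    """Too few observations for the number of free parameters."""


class SchemaError(ValueError):
    """An input table is missing required columns or contains malformed cells."""


class AnalysisError(RuntimeError):
    """A pipeline run could not produce a report."""
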