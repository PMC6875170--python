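"""Exception hierarchy shared across the package."""


class TescopeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TescopeError):
    """A file does not conform to its declared format."""


class ValidationError(TescopeError):
    """An in-memory record violates its invariants."""


class ParameterError(TescopeError):
    """A parameter is outside its documented domain."""


class FeasibilityError(TescopeError):
    """Jointly infeasible generator targets; message lists the attainable range."""


class PlacementError(TescopeError):
    """Planted insertions overlap after realization; retry with a new seed."""


class UndefinedStatisticError(TescopeError):
    """A statistic has an empty denominator or no informative observations."""


class ConfigError(TescopeError):
    """Pipeline configuration is missing or malformed."""
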