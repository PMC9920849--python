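"""Exception hierarchy shared across the package."""


class GourdstatsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GourdstatsError, ValueError):
    """Invalid trial or run configuration (negative variance, bad counts...)."""


class DataFormatError(GourdstatsError, ValueError):
    """Malformed input table: missing column, non-numeric value field."""


class DesignError(GourdstatsError, ValueError):
    """Data incompatible with the requested experimental-design analysis."""


class InsufficientDataError(GourdstatsError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(GourdstatsError, ValueError):
    """The statistic is undefined on this input (e.g. zero variance)."""
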