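"""Exception types shared across the package."""


class DepreconError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DepreconError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DomainError(DepreconError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class TariffError(DepreconError, KeyError):
    """A utilization category or calendar year is missing from a price table."""


class CohortError(DepreconError, ValueError):
    """A cohort does not satisfy the preconditions of an analysis stage."""
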