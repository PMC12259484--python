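"""Exception hierarchy.

Every malformed input raises exactly one of these typed errors, so callers
(and the CLI) can distinguish bad data from bad configuration.
"""


class RiskdetError(Exception):
    """Base class for all package errors."""


class SchemaError(RiskdetError):
    """A file or record violates the documented interchange schema."""


class ValidationError(RiskdetError):
    """A structurally well-formed record violates a domain invariant."""


class ConfigError(RiskdetError):
    """A configuration object (weights, rules, simulation config) is invalid."""


class InsufficientDataError(RiskdetError):
    """Too few observations to compute the requested statistic."""


class UndefinedStatisticError(RiskdetError):
    """The statistic is undefined for this input (e.g. constant vector)."""
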