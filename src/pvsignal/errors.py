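"""Exception hierarchy shared across the package."""


class PvSignalError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PvSignalError):
    """Bad dialect, column map, or pipeline configuration."""


class UndefinedRuleError(PvSignalError):
    """A rule statistic is undefined (zero antecedent or marginal support)."""


class UnsatisfiableSpecError(PvSignalError):
    """A synthetic-cohort specification cannot be realized exactly."""


class GmtParseError(PvSignalError):
    """A gene-set file line does not follow the GMT layout."""
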