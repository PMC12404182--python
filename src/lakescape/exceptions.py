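"""Exception hierarchy shared by all pipeline stages."""


class LakescapeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LakescapeError, ValueError):
    """Invalid generator or pipeline configuration."""


class DomainError(LakescapeError, ValueError):
    """Input outside the mathematical domain of an operation."""


class IncompleteYearError(LakescapeError):
    """A watershed-year (or watershed-period) is missing one or more months."""


class ModelError(LakescapeError):
    """A statistical model cannot be fitted on the supplied data."""
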