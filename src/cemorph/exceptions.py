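"""Exception hierarchy shared across the package."""


class CemorphError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CemorphError, ValueError):
    """A cohort or measurement configuration field is invalid."""


class UndefinedStatisticError(CemorphError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class DegenerateDesignError(CemorphError, ValueError):
    """A regression design matrix is singular (e.g. all ages identical)."""


class AlignmentError(CemorphError, ValueError):
    """Two paired series do not share the same unit labels."""


class FormatError(CemorphError, ValueError):
    """An input file does not conform to its expected format."""
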