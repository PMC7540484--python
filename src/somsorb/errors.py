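"""Exception hierarchy shared by all analysis stages."""


class SomsorbError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SomsorbError, ValueError):
    """Input violates a documented precondition."""


class EstimationError(SomsorbError, RuntimeError):
    """A numerical estimator failed (e.g. no physical CGI crossing)."""


class UndefinedStatisticError(SomsorbError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class TableParseError(SomsorbError, ValueError):
    """A tabular or coordinate file could not be parsed."""
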