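"""Exception hierarchy.

Every error raised by the package derives from :class:`GreyKappaError` so
callers (and the CLI) can distinguish package errors from programming errors.
"""


class GreyKappaError(Exception):
    """Base class for all greykappa errors."""


class InvalidDimensionError(GreyKappaError, ValueError):
    """A table, weight matrix or category count has an unusable dimension."""


class EmptyTableError(GreyKappaError, ValueError):
    """A contingency table with zero total count cannot be normalized."""


class UndefinedCoefficientError(GreyKappaError, ValueError):
    """Chance agreement equals 1, so the coefficient is undefined."""


class UndefinedCVError(GreyKappaError, ValueError):
    """Coefficient of variation is undefined (zero mean)."""


class InsufficientDataError(GreyKappaError, ValueError):
    """Fewer values than the statistic requires."""


class InvalidCorrelationError(GreyKappaError, ValueError):
    """Latent correlation outside (-1, 1)."""


class InvalidCutoffError(GreyKappaError, ValueError):
    """Cutoff quantiles are not strictly increasing inside (0, 1)."""


class InvalidSizeError(GreyKappaError, ValueError):
    """Sample size below 1."""


class UnreachableTargetError(GreyKappaError, ValueError):
    """Target agreement below the reachable lower bound of the PA search."""


class NonConvergenceError(GreyKappaError, RuntimeError):
    """A search exhausted its evaluation budget without meeting tolerance."""


class TableParseError(GreyKappaError, ValueError):
    """A counts CSV could not be parsed into a square integer table."""


class UndefinedMAPEError(GreyKappaError, ValueError):
    """MAPE requested for a true coefficient of exactly zero."""
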