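"""Exception hierarchy for gblupcv.

All data and numerical failures raise subclasses of :class:`GblupcvError`
so callers (and the CLI) can distinguish bad input from bugs.
"""


class GblupcvError(Exception):
    """Base class for all gblupcv errors."""


class DataError(GblupcvError):
    """Invalid or inconsistent input data (parsing, ids, missingness)."""


class NumericalRankError(GblupcvError):
    """A matrix that must be nonsingular / positive definite is not.

    The message names the offending matrix and, where applicable, a remedy
    (e.g. switch model, enable jitter).
    """


class DegenerateLeverageError(GblupcvError):
    """A leverage value is numerically 1: the observation predicts itself
    and the closed-form leave-one-out residual is undefined."""


class DegeneratePredictionError(GblupcvError):
    """The strategy-II residual denominator vanished for some individual."""


class UndefinedStatisticError(GblupcvError):
    """A requested summary (e.g. a correlation over <2 points or over a
    constant prediction vector) is mathematically undefined."""
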