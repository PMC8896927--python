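"""Exception hierarchy for the lgcw package."""


class LgcwError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LgcwError, ValueError):
    """A parameter violates its documented constraints."""


class ShapeError(LgcwError, ValueError):
    """Array dimensions are inconsistent."""


class DegenerateRegionError(LgcwError):
    """A cluster region has (numerically) zero total membership weight."""


class DegenerateFitError(LgcwError):
    """The bias-field normal equations have a zero denominator somewhere."""


class InitializationError(LgcwError):
    """Level-set initialization produced an empty region."""


class OptimizationFailureError(LgcwError):
    """Energy increased beyond tolerance for several consecutive iterations.

    Carries the iteration trace in ``trace`` (list of per-iteration energies).
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class EmptyRegionError(LgcwError):
    """A mask expected to contain foreground pixels is empty."""


class MarkerError(LgcwError):
    """Watershed was invoked without any marker."""


class DegenerateTableError(LgcwError, ValueError):
    """A contingency table has a zero margin."""


class UndefinedStatisticError(LgcwError, ZeroDivisionError):
    """A test statistic is undefined for the given inputs."""
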