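"""Exception hierarchy shared by all stages of the pipeline."""


class RavenshortError(Exception):
    """Base class for all package errors."""


class ParseError(RavenshortError, ValueError):
    """A response table could not be parsed; the message names the offending row/column."""


class ConfigurationError(RavenshortError, ValueError):
    """A run or generator configuration is invalid or inconsistent with the data."""


class DataError(RavenshortError, ValueError):
    """The data violate a precondition of an operation (e.g. incomplete matrix)."""


class UndefinedStatisticError(RavenshortError, ValueError):
    """A requested statistic is undefined on the given input (e.g. zero-variance correlation)."""


class ConvergenceError(RavenshortError, RuntimeError):
    """An iterative routine failed to reach its tolerance.

    Attributes carry the best achieved state so callers can report it.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class NoSolutionError(RavenshortError, RuntimeError):
    """The grid search produced no candidate form within the length cap."""
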