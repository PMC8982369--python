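"""Exception hierarchy for gpforward."""


class GpForwardError(Exception):
    """Base class for all package errors."""


class ParameterError(GpForwardError, ValueError):
    """Invalid user-supplied parameter."""


class DesignError(GpForwardError, ValueError):
    """Population or study design that cannot be realized."""


class QcError(GpForwardError):
    """Quality control left no usable data.

    Carries the partial report so callers can inspect what was removed.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class ConfoundingError(GpForwardError, ValueError):
    """Rank-deficient fixed-effect design; lists aliased columns."""

    def __init__(self, message, aliased=()):
        super().__init__(message)
        self.aliased = list(aliased)


class NumericalError(GpForwardError, ArithmeticError):
    """Singular or non-PSD matrix where a solvable system was required."""


class McmcError(GpForwardError, RuntimeError):
    """Divergent or non-finite state inside an MCMC chain."""

    def __init__(self, message, iteration=None):
        super().__init__(message)
        self.iteration = iteration


class SchemaError(GpForwardError, KeyError):
    """Input table/matrix does not match the expected column schema."""
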