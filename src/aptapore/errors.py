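"""Exception hierarchy.

Everything raised on bad scientific input derives from :class:`AptaporeError`
so callers can catch one base class at pipeline boundaries.
"""


class AptaporeError(Exception):
    """Base class for all package errors."""


class RangeError(AptaporeError, ValueError):
    """A requested evaluation point lies outside the data range."""


class UndefinedRatioError(AptaporeError, ZeroDivisionError):
    """A ratio (rectification, response) is undefined because a current is zero."""


class PreconditionError(AptaporeError, ValueError):
    """An operation's documented precondition is violated."""


class FormatError(AptaporeError, ValueError):
    """A delimited-text file does not match the expected dialect."""


class ConvergenceError(AptaporeError, RuntimeError):
    """The PNP solver failed to converge; carries the residual history."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])
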