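"""Exception hierarchy."""


class MarkovPOTError(Exception):
    """Base class for all package errors."""


class FormatError(MarkovPOTError, ValueError):
    """Malformed input table or report."""


class EmptyDatasetError(MarkovPOTError, ValueError):
    """Parsing produced no usable series."""


class ConvergenceError(MarkovPOTError, RuntimeError):
    """An optimizer or root finder failed to converge.

    Carries the optimizer trace (if any) in ``trace``.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
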