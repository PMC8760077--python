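"""Exception hierarchy shared across the pipeline."""


class TraplineError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TraplineError):
    """A file does not conform to the expected layout (missing column, short line)."""


class ValidationError(TraplineError):
    """A value violates a domain invariant (negative count, out-of-range score)."""


class FitError(TraplineError):
    """Nonlinear fitting failed or its preconditions were not met."""

    def __init__(self, message, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate
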