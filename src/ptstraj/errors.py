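"""Exception types shared across the package."""


class PtstrajError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(PtstrajError, ValueError):
    """A simulation or run configuration field is invalid.

    Carries the offending field name so callers can report it precisely.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DataFormatError(PtstrajError, ValueError):
    """A data file could not be parsed; ``lines`` holds offending line numbers."""

    def __init__(self, message: str, lines=None):
        self.lines = list(lines) if lines is not None else []
        if self.lines:
            message = f"{message} (line(s) {', '.join(map(str, self.lines))})"
        super().__init__(message)


class DegenerateClassError(PtstrajError, RuntimeError):
    """An EM start collapsed: a class lost essentially all weight or a
    residual variance fell below the configured floor."""


class ConvergenceError(PtstrajError, RuntimeError):
    """An iterative fit failed to converge; ``diagnostics`` holds partial state."""

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics
        super().__init__(message)


class RankDeficiencyError(PtstrajError, ValueError):
    """A regression design matrix is rank deficient; names collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(map(str, self.columns))
        )
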