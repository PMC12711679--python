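"""Exception hierarchy shared across the package."""


class BinetError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BinetError, ValueError):
    """Input violates a documented precondition (wrong size, bad value)."""


class DegenerateFitError(BinetError):
    """A step fit is undefined because the series carries no step (constant)."""


class MissingThresholdError(BinetError, KeyError):
    """A gene required for discretization has no usable threshold."""


class DegenerateMarginalError(BinetError):
    """A quadrant table has a zero row or column marginal."""


class UndefinedFDRError(BinetError):
    """FDR ratio requested but the observed network has no discoveries."""


class InconsistencyError(BinetError):
    """Conflicting implication records for the same gene pair."""


class DegenerateSplitError(BinetError):
    """A score split put every sample on one side."""


class InfeasibleError(BinetError):
    """Planted implication constraints contradict each other."""


class NonConvergenceError(BinetError):
    """Iterative search exhausted its budget without meeting the target."""


class ParseError(BinetError, ValueError):
    """A text input file is malformed; carries file and line context."""

    def __init__(self, path, line_no, message):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{self.path}:{line_no}: {message}")


class PipelineError(BinetError):
    """A pipeline stage failed; names the stage and wraps the cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
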