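"""Exception hierarchy shared across the package.

Validation problems (bad tables, bad configs) and fit problems (EM could
not produce a usable mixture) are kept distinct so callers — in particular
the command-line layer — can map them to different exit codes.
"""


class PullcallError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PullcallError):
    """Input data or configuration violates a documented invariant."""


class FormatError(ValidationError):
    """A table file does not match the declared dialect (e.g. missing column)."""


class FitError(PullcallError):
    """The mixture model could not be fitted or is unusable downstream."""


class InsufficientDataError(FitError):
    """Too few observations to fit the requested number of components."""


class NotConvergedError(FitError):
    """A downstream step required a converged fit but the fit did not converge."""


class PipelineStageError(PullcallError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
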