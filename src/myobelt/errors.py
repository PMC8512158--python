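"""Exception hierarchy.

Everything user-facing derives from :class:`MyobeltError` so callers (and the
CLI, which maps validation failures to exit code 2) can catch one type.
"""


class MyobeltError(Exception):
    """Base class for all package errors."""


class ValidationError(MyobeltError, ValueError):
    """Invalid input data or configuration."""


class DegenerateDesignError(ValidationError):
    """A fit was requested on a design that cannot identify the parameters."""


class PipelineStageError(MyobeltError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
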