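"""Exception types shared across the package."""


class RootmorphError(Exception):
    """Base class for all package errors."""


class ParameterError(RootmorphError, ValueError):
    """An argument violates a precondition (bad bounds, non-positive size, ...)."""


class EmptyInputError(RootmorphError, ValueError):
    """An operation received an input with no content (all-zero histogram, ...)."""


class UndefinedMeasurementError(RootmorphError):
    """A quantity is undefined for this input (e.g. diameter with no circles).

    Raised rather than returning 0 so downstream consumers see a missing
    value instead of a silently wrong zero.
    """


class PipelineError(RootmorphError):
    """A preprocessing stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
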