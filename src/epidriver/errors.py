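"""Exception hierarchy shared across the pipeline."""


class EpidriverError(Exception):
    """Base class for all package errors."""


class ParseError(EpidriverError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(EpidriverError, ValueError):
    """Input violated a documented invariant."""


class UndefinedValueError(EpidriverError, ValueError):
    """A quantity is undefined for the given input (e.g. mean over zero CpGs)."""


class StageError(EpidriverError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
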