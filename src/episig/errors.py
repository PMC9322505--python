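"""Exception hierarchy shared across the pipeline stages."""


class EpisigError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(EpisigError):
    """Invalid configuration value; the message names the offending field."""


class ParameterError(EpisigError):
    """An operation parameter is outside its documented domain."""


class InputError(EpisigError):
    """Input data violates a precondition (missing probes, empty groups, ...)."""


class DegenerateDataError(EpisigError):
    """Data admits no meaningful estimate (e.g. all residual variances zero)."""


class StageError(EpisigError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
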