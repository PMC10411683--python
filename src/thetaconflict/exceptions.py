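"""Exception hierarchy for the pipeline."""


class ThetaConflictError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ThetaConflictError, ValueError):
    """An input violates a documented precondition."""


class DegenerateInputError(ThetaConflictError, ValueError):
    """A statistic is undefined for this input (e.g. zero variance)."""


class ConfigurationError(ThetaConflictError, ValueError):
    """A configuration value is inconsistent or out of range."""


class PipelineError(ThetaConflictError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
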