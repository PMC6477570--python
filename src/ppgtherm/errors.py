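"""Exception taxonomy for the extraction and inference pipeline."""


class PpgThermError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PpgThermError, ValueError):
    """A signal or table violates a precondition (shape, length, monotonicity)."""


class ConfigurationError(PpgThermError, ValueError):
    """An option value is outside its allowed set."""


class UndefinedRatioError(PpgThermError, ArithmeticError):
    """A spectral ratio is requested for a zero-power signal."""


class PipelineStageError(PpgThermError, RuntimeError):
    """Wraps a failure inside a named stage of a composed pipeline."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
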