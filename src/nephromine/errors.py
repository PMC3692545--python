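"""Exception types shared across the pipeline."""


class NephromineError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NephromineError, ValueError):
    """An invalid simulation or pipeline configuration value."""


class InputError(NephromineError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateProteinError(NephromineError):
    """A protein with no observable tryptic peptide; it cannot receive an emPAI."""


class PipelineStageError(NephromineError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
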