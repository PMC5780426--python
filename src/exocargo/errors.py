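"""Exception hierarchy shared across the pipeline stages."""


class ExocargoError(Exception):
    """Base class for all errors raised by exocargo."""


class FormatError(ExocargoError):
    """An input file does not match the expected dialect."""


class ValidationError(ExocargoError):
    """Parsed data violates a structural invariant."""


class StageError(ExocargoError):
    """A pipeline stage failed; carries the stage name for provenance."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
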