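"""Exception types shared across the pipeline."""


class MirpairError(Exception):
    """Base class for all pipeline errors."""


class ParseError(MirpairError):
    """A file could not be parsed; the message names the offending row/column/id."""


class ConfigurationError(MirpairError):
    """An infeasible or inconsistent configuration was supplied."""


class StageError(MirpairError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
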