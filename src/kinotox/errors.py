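"""Exception types shared across the pipeline."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class DegenerateBlankError(InvalidArgumentError):
    """Blank-well mean is zero, so (raw - blank)/blank is undefined."""


class NoBeatsError(RuntimeError):
    """A force trace contains no detectable beat."""


class DivergedError(RuntimeError):
    """Levenberg-Marquardt training produced a non-finite loss."""


class StageInputError(RuntimeError):
    """A pipeline stage is missing the outputs of an earlier stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
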