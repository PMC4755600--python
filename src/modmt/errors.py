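"""Exception hierarchy for modmt.

Every error a pipeline stage can raise derives from :class:`ModmtError`
so the orchestrator can attach the stage name and fail cleanly.
"""


class ModmtError(Exception):
    """Base class for all modmt errors."""


class InvalidSequenceError(ModmtError):
    """Empty sequence, or a letter outside the expected alphabet.

    Carries the offending character and its 1-based position when known.
    """

    def __init__(self, message: str, char: str | None = None, position: int | None = None):
        super().__init__(message)
        self.char = char
        self.position = position


class InvalidProfileError(ModmtError):
    """A Cys-box profile that cannot be matched (e.g. empty gap signature)."""


class NoAlignmentError(ModmtError):
    """Spliced alignment found no collinear chain above minimum coverage."""


class NonCanonicalSpliceError(ModmtError):
    """A gap between exons admits no GT..AG placement under enforcement."""


class InvalidMotifError(ModmtError):
    """A promoter motif contains letters outside the IUPAC nucleotide code."""


class UnknownMetalError(ModmtError):
    """A stoichiometry references an element with no MetalSpec."""


class UnknownBoxKindError(ModmtError):
    """An architecture contains a box kind with no Cu capacity rule."""


class NoControlError(ModmtError):
    """A growth table lacks the zero-dose control required for normalization."""


class InfeasibleSpecError(ModmtError):
    """A synthetic-gene spec whose exon/intron ranges cannot tile the sequence."""


class PipelineStageError(ModmtError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
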