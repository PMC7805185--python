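"""Exception hierarchy for semipep."""


class SemipepError(Exception):
    """Base class for all semipep errors."""


class FormatError(SemipepError):
    """A table or FASTA file does not conform to the expected dialect."""


class AnnotationError(SemipepError):
    """An accession or taxid cannot be resolved during annotation."""


class ConsistencyError(SemipepError):
    """Internal cross-table consistency violated (e.g. quantitation engine
    lacks a record for a consensus sequence)."""


class ClassificationError(SemipepError):
    """A residue character outside the 20-letter alphabet (or the terminus
    sentinels) was encountered during tryptic classification."""


class ContractError(SemipepError):
    """An operation was called outside its stated preconditions."""


class StageError(SemipepError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
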