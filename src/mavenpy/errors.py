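"""Exception hierarchy for validation and pipeline failures.

Every invariant violation raises a distinct, named error so callers (and the
pipeline orchestrator) can report the offending stage and object precisely.
"""


class MavenError(Exception):
    """Base class for all package errors."""


class ValidationError(MavenError):
    """An input object violates one of its declared invariants."""


class ShapeMismatchError(ValidationError):
    """Volume/stack shapes disagree (between mask files, or stack vs atlas)."""


class EmptyRegionError(ValidationError):
    """A region mask has no voxels (e.g. a label value absent from the volume)."""


class DuplicateRegionError(ValidationError):
    """Two rows of the region table share a region_id."""


class UnknownRegionError(ValidationError):
    """A region_id was requested that the atlas or matrix does not contain."""


class DuplicateSubjectError(ValidationError):
    """Two rows of the subject table (or two stacks) share a subject_id."""


class PhenotypeLevelsError(ValidationError):
    """The phenotype column does not reduce to exactly two levels."""


class MatrixFormatError(ValidationError):
    """A signal-matrix file has a non-numeric, blank, or ragged entry."""


class SingleClassError(ValidationError):
    """A model fit or split was attempted with only one phenotype class."""


class AllRegionsDroppedError(MavenError):
    """Every region column was removed; the pipeline cannot continue."""


class PipelineStageError(MavenError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause!r}")
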