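"""Exception hierarchy shared across the package."""


class BiotypeGCNError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BiotypeGCNError):
    """Invalid user-supplied configuration (weights, proportions, schema)."""


class InfeasibleCohortError(ConfigurationError):
    """Cohort specification that cannot be instantiated (e.g. fewer patients than subtypes)."""


class DataShapeError(BiotypeGCNError):
    """Array dimensions or symmetry requirements violated."""


class ZeroVarianceError(DataShapeError):
    """A component time course (or feature column) is constant."""


class InsufficientSamplesError(DataShapeError):
    """Too few time points / observations for the requested computation."""


class IllConditionedSampleError(DataShapeError):
    """Requested fewer time points than components when sampling time courses."""


class CollinearityError(BiotypeGCNError):
    """Rank-deficient covariate design."""

    def __init__(self, message, dependent_columns=None):
        super().__init__(message)
        self.dependent_columns = dependent_columns or []


class DegenerateGraphError(BiotypeGCNError):
    """Population graph unusable for training (e.g. all-zero adjacency)."""


class DegenerateGraphWarning(UserWarning):
    """Graph is suspicious (all-zero adjacency) but training was not requested."""


class InvalidAdjacencyError(DataShapeError):
    """Adjacency violates non-negativity or symmetry."""


class DivergenceError(BiotypeGCNError):
    """Training produced a non-finite loss."""

    def __init__(self, message, epoch=None):
        super().__init__(message)
        self.epoch = epoch


class EmptyClusterError(BiotypeGCNError):
    """A cluster repeatedly lost all members during joint training."""


class AssignmentError(BiotypeGCNError):
    """A point lacks a cluster assignment, or assignments are inconsistent."""


class ProjectionError(DataShapeError):
    """Template projection dimension mismatch."""


class PartitionError(BiotypeGCNError):
    """Component index outside the network partition."""


class UndefinedCorrelationError(BiotypeGCNError):
    """Correlation requested on a zero-variance vector."""


class UndefinedEffectError(BiotypeGCNError):
    """Effect size undefined (zero pooled standard deviation)."""


class UndefinedReductionError(BiotypeGCNError):
    """Reduction rate undefined because the baseline score is zero."""


class MissingAssignmentError(BiotypeGCNError):
    """A longitudinal subject has no biotype assignment."""


class ChecksumError(BiotypeGCNError):
    """A file failed its checksum sidecar verification."""
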