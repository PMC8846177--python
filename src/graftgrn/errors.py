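"""Exception hierarchy shared across the pipeline stages."""


class GraftGRNError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(GraftGRNError, ValueError):
    """A configuration value violates its documented constraints."""


class MissingSampleError(GraftGRNError, KeyError):
    """A referenced sample ID is absent from the expression matrix."""


class InsufficientDataError(GraftGRNError, ValueError):
    """Too few samples/replicates for the requested computation."""


class UnknownTermError(GraftGRNError, KeyError):
    """A GO term ID is not present in the term graph."""


class DegenerateTableError(GraftGRNError, ValueError):
    """A contingency table has a zero margin and cannot be tested."""


class NoValidPartitionError(GraftGRNError, ValueError):
    """No outlier/nonoutlier assignment yields a finite statistic."""


class AnnotationError(GraftGRNError, KeyError):
    """A required node annotation (e.g. TF family) is missing."""


class DependencyError(GraftGRNError, RuntimeError):
    """A workflow stage's required upstream artifact is missing."""
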