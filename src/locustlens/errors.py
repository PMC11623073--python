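"""Exception hierarchy for the locustlens pipeline.

Every stage raises a subclass of :class:`LocustLensError` so CLI wrappers can
report the failing stage with a non-zero exit status.
"""


class LocustLensError(Exception):
    """Base class for all pipeline errors."""


class ContractError(LocustLensError):
    """A documented precondition was violated by the caller."""


class SizingError(LocustLensError):
    """A requested geometry or span cannot be constructed."""


class FormatError(LocustLensError):
    """An input file does not match the expected on-disk layout."""


class GridValidationError(LocustLensError):
    """A climate grid violates its axis or value invariants."""


class TemporalCoverageError(LocustLensError):
    """A (year, month) query falls outside the climate grid's span."""


class SpatialCoverageError(LocustLensError):
    """A coordinate query falls too far outside the climate grid's box."""


class EmptyOutputError(LocustLensError):
    """A stage produced zero rows where downstream stages need at least one."""


class MappingError(LocustLensError):
    """A named region cannot be resolved against the atlas."""


class ConsistencyError(LocustLensError):
    """The same region-month carries both a presence and an absence label."""


class StratificationError(LocustLensError):
    """A class is too small for the requested number of stratified folds."""


class UndefinedMetricError(LocustLensError):
    """A metric (e.g. AUC with a single truth class) is undefined."""
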