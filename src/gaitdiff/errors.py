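"""Exception hierarchy.

Every anticipated failure mode raises a named subclass of :class:`GaitError`
so callers (and the pipeline orchestrator) can distinguish bad inputs from
bugs.
"""


class GaitError(Exception):
    """Base class for all gaitdiff errors."""


class InvalidSpecError(GaitError):
    """A cohort specification violates its invariants."""


class FilterLengthError(GaitError):
    """Series too short for the requested zero-lag filter."""


class InvalidParameterError(GaitError):
    """A numeric parameter is outside its admissible range."""


class DegenerateConfigurationError(GaitError):
    """Marker configuration unsuitable for rigid-body fitting (<3 markers or collinear)."""


class MissingMarkerError(GaitError):
    """A required marker is absent from a trial."""


class NoEventsError(GaitError):
    """No gait events could be detected (e.g. monotone marker trajectory)."""


class InsufficientStridesError(GaitError):
    """Fewer complete gait cycles available than requested."""


class InvalidCycleError(GaitError):
    """A gait cycle contains non-finite values or has the wrong length."""


class CountMismatchError(GaitError):
    """Number of per-stride feature sets differs from the expected stride count."""


class MissingMetadataError(GaitError):
    """Required subject metadata (e.g. affected side) is absent."""


class MissingWaveformError(GaitError):
    """A subject lacks one of the required joint/plane waveforms."""


class DegenerateColumnError(GaitError):
    """A feature column has zero variance and cannot be standardized."""


class InsufficientRowsError(GaitError):
    """Too few observations for the requested decomposition."""


class InvalidGroupingError(GaitError):
    """Group labels unsuitable for the requested test (group with <2 members, <2 groups)."""


class InvalidPValueError(GaitError):
    """A p-value lies outside [0, 1]."""


class InfiniteEffectError(GaitError):
    """Cohen's d undefined: both SDs zero with unequal means."""


class InvalidLabelsError(GaitError):
    """Class labels are not a two-class vector with >=2 members per class."""


class StratificationError(GaitError):
    """Cross-validation folds cannot contain both classes."""


class EmptyFeatureError(GaitError):
    """Feature selection invoked with zero candidate features."""


class FormatError(GaitError):
    """A data file does not conform to the documented dialect."""
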