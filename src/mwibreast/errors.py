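"""Exception hierarchy for mwibreast.

All package-specific failures derive from :class:`MwiBreastError` so callers
can catch one base class at CLI or script level.
"""


class MwiBreastError(Exception):
    """Base class for all mwibreast errors."""


class FormatError(MwiBreastError):
    """A file does not conform to the expected on-disk format."""


class DimensionalityError(FormatError):
    """A volume does not have the expected number of dimensions."""


class ConsistencyError(MwiBreastError):
    """Two objects that must share geometry (shape/spacing/origin) do not."""


class ParameterError(MwiBreastError):
    """A parameter value is outside its admissible range."""


class SeedNotFoundError(MwiBreastError):
    """An automatic seed search produced no qualifying voxel."""


class EmptyRegionError(MwiBreastError):
    """Region growing started from a background voxel or produced nothing."""


class InsufficientDataError(MwiBreastError):
    """Too few samples to fit a statistical model reliably."""


class FrequencyGridError(ParameterError):
    """A requested frequency is not on the 3-10 GHz / 0.01 GHz grid."""


class PlacementError(MwiBreastError):
    """A synthetic structure does not fit inside its host region."""


class VocabularyError(MwiBreastError):
    """A label map contains a code outside its declared vocabulary."""


class MetadataError(MwiBreastError):
    """Required per-object metadata (e.g. tumor kind) is missing."""


class TableError(MwiBreastError):
    """A tissue label has no entry in the dielectric parameter table."""


class FitError(MwiBreastError):
    """An iterative fit failed to converge."""
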