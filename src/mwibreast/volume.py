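"""Core in-memory containers: 3D volumes, exam bundles, label vocabularies.

Arrays are stored in ``(z, y, x)`` index order (slice-major); the physical
position of voxel ``(z, y, x)`` is ``origin + (x*sx, y*sy, z*sz)`` using the
voxel-center convention, matching ITK semantics.  ``y`` is the
anterior-posterior axis (``y`` increases toward the chest wall in the prone
geometry used throughout), ``x`` is lateral and ``z`` is the slice axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConsistencyError, VocabularyError

#: dtypes a Volume3D may carry and their MetaImage element-type names
SUPPORTED_DTYPES: Mapping[str, str] = {
    "int16": "MET_SHORT",
    "float32": "MET_FLOAT",
    "float64": "MET_DOUBLE",
}

# Simple-dialect label vocabulary: the breast is reduced to a single
# fat+fibroglandular compartment.
SIMPLE_LABELS: Mapping[int, str] = {
    -4: "benign_tumor",
    -3: "malignant_tumor",
    -2: "skin",
    -1: "muscle",
    0: "background",
    1: "fat_plus_fibroglandular",
}

# Detailed-dialect vocabulary: three water-content subclasses per breast
# tissue plus a transition class between fat and fibroglandular tissue.
DETAILED_LABELS: Mapping[int, str] = {
    -4: "benign_tumor",
    -3: "malignant_tumor",
    -2: "skin",
    -1: "muscle",
    0: "background",
    1: "fibroglandular_low",
    2: "fibroglandular_median",
    3: "fibroglandular_high",
    4: "transition",
    5: "fat_low",
    6: "fat_median",
    7: "fat_high",
}


@dataclass
class LabelVocabulary:
    dialect: str
    entries: Mapping[int, str]


SIMPLE_VOCABULARY = LabelVocabulary("simple", SIMPLE_LABELS)
DETAILED_VOCABULARY = LabelVocabulary("detailed", DETAILED_LABELS)


@dataclass
class Volume3D:
    """A 3D scalar grid with spacing/origin metadata.

    Parameters
    ----------
    data:
        3D array in ``(z, y, x)`` order; dtype must be int16, float32 or
        float64.
    spacing:
        Voxel size ``(sx, sy, sz)`` in mm, strictly positive.
    origin:
        Physical position ``(ox, oy, oz)`` in mm of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConsistencyError(
                f"Volume3D requires a 3D array, got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ConsistencyError("Volume3D dimensions must each be >= 1")
        if self.data.dtype.name not in SUPPORTED_DTYPES:
            raise ConsistencyError(
                f"unsupported element type {self.data.dtype.name!r}; "
                f"expected one of {sorted(SUPPORTED_DTYPES)}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ConsistencyError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ConsistencyError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def element_type(self) -> str:
        return self.data.dtype.name

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Return a new volume with the same geometry and different data."""
        return Volume3D(data, self.spacing, self.origin)

    def same_geometry(self, other: "Volume3D", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def check_same_geometry(*volumes: Volume3D) -> None:
    """Raise :class:`ConsistencyError` unless all volumes share geometry."""
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_geometry(v):
            raise ConsistencyError(
                f"volumes do not share geometry: {ref.shape}/{ref.spacing} vs "
                f"{v.shape}/{v.spacing}"
            )


@dataclass
class ExamBundle:
    """Co-registered channels of one exam.

    ``I``, ``F`` and ``W`` are the Dixon in-phase, fat-only and water-only
    channels; ``subtraction`` is the contrast-enhanced subtraction volume in
    which tumors enhance.  All four must share shape, spacing and origin.
    """

    I: Volume3D  # noqa: E741 - field named after the Dixon channel
    F: Volume3D
    W: Volume3D
    subtraction: Volume3D
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_same_geometry(self.I, self.F, self.W, self.subtraction)

    @property
    def channels(self) -> dict[str, Volume3D]:
        return {"I": self.I, "F": self.F, "W": self.W, "subtraction": self.subtraction}

    def replace_channels(self, **channels: Volume3D) -> "ExamBundle":
        kwargs = dict(self.channels)
        kwargs.update(channels)
        return ExamBundle(
            I=kwargs["I"],
            F=kwargs["F"],
            W=kwargs["W"],
            subtraction=kwargs["subtraction"],
            metadata=dict(self.metadata),
        )


def validate_labels(labels: Volume3D, vocabulary: LabelVocabulary) -> None:
    """Check that every voxel of ``labels`` uses a code of ``vocabulary``."""
    if not np.issubdtype(labels.data.dtype, np.integer):
        raise VocabularyError("label maps must carry an integer element type")
    present = set(np.unique(labels.data).tolist())
    unknown = present - set(vocabulary.entries)
    if unknown:
        raise VocabularyError(
            f"labels {sorted(unknown)} are not part of the "
            f"{vocabulary.dialect!r} vocabulary"
        )


def simple_from_detailed(labels: Volume3D) -> Volume3D:
    """Collapse a detailed-dialect label map to the simple dialect.

    Breast-interior classes 1-7 (fibroglandular subclasses, transition and
    fat subclasses) all become label 1 (fat + fibroglandular); tumors, skin,
    muscle and background are unchanged.
    """
    validate_labels(labels, DETAILED_VOCABULARY)
    out = labels.data.copy()
    out[(out >= 1) & (out <= 7)] = 1
    return labels.with_data(out.astype(np.int16))
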