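"""Tumor segmentation from contrast-enhanced subtraction volumes.

Enhancing lesions are grown from seeds by running-mean region growing
(clipped to the breast region), labeled into clusters with the
Hoshen-Kopelman union-find algorithm, sized, and overlaid on the anatomy
label map (benign -> -4, malignant -> -3).  Within one exam, tumors sharing
a kind are ranked by volume and named XS < S < M < L < XL.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._grow import region_grow
from .errors import EmptyRegionError, MetadataError, ParameterError
from .volume import Volume3D

SIZE_CLASSES = ("XS", "S", "M", "L", "XL")

#: clusters smaller than this are discarded as noise (below the ~0.5 cm
#: smallest reported lesion size)
MIN_CLUSTER_VOXELS = 5


@dataclass
class TumorRecord:
    """Metadata of one segmented tumor cluster."""

    cluster_id: int
    kind: str                      # "benign" | "malignant"
    voxel_count: int
    equivalent_diameter_cm: float  # diameter of the equal-volume sphere
    centroid_mm: tuple[float, float, float]  # physical (x, y, z)
    size_class: str | None = None
    laterality: str = "left"

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ParameterError("voxel_count must be >= 1")
        if self.kind not in ("benign", "malignant"):
            raise MetadataError(f"unknown tumor kind {self.kind!r}")


def equivalent_diameter_cm(voxel_count: int, voxel_volume_mm3: float) -> float:
    """Diameter (cm) of the sphere with the same volume as the cluster."""
    volume_cm3 = voxel_count * voxel_volume_mm3 / 1000.0
    return (6.0 * volume_cm3 / np.pi) ** (1.0 / 3.0)


def grow_tumor_candidates(
    subtraction: Volume3D,
    breast_region: np.ndarray,
    seeds: list[tuple[int, int, int]],
    tol: float = 0.15,
) -> np.ndarray:
    """Union of 6-connected regions grown from each seed, clipped to the
    breast region."""
    breast_region = breast_region.astype(bool)
    for seed in seeds:
        if not breast_region[seed]:
            raise EmptyRegionError(
                f"tumor seed {seed} lies outside the breast region"
            )
    mask = np.zeros(subtraction.shape, dtype=bool)
    for seed in seeds:
        mask |= region_grow(
            subtraction.data.astype(np.float64), [seed], tol, allowed=breast_region
        )
    return mask


def hoshen_kopelman_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Single-pass union-find labeling of 6-connected clusters.

    Returns (cluster id volume, cluster count); ids are 1..K in descending
    voxel-count order (the largest cluster is 1).
    """
    mask = mask.astype(bool)
    shape = mask.shape
    nz, ny, nx = shape
    sz, sy = ny * nx, nx
    flat = mask.ravel()
    labels = np.zeros(flat.shape, dtype=np.int32)
    parent: list[int] = [0]  # parent[i] for provisional label i; 0 unused

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    occupied = np.flatnonzero(flat)
    for f in occupied:
        z = f // sz
        rem = f - z * sz
        y = rem // sy
        x = rem - y * sy
        roots = set()
        if z > 0 and labels[f - sz]:
            roots.add(find(labels[f - sz]))
        if y > 0 and labels[f - sy]:
            roots.add(find(labels[f - sy]))
        if x > 0 and labels[f - 1]:
            roots.add(find(labels[f - 1]))
        if not roots:
            parent.append(len(parent))
            labels[f] = len(parent) - 1
        else:
            keep = min(roots)
            labels[f] = keep
            for r in roots:
                parent[r] = keep

    if not occupied.size:
        return labels.reshape(shape), 0

    # resolve provisional labels to their roots
    root_of = np.zeros(len(parent), dtype=np.int32)
    for i in range(1, len(parent)):
        root_of[i] = find(i)
    resolved = root_of[labels[occupied]]

    # relabel 1..K by descending cluster size (ties: first-seen root order)
    roots, inverse, counts = np.unique(
        resolved, return_inverse=True, return_counts=True
    )
    order = np.argsort(-counts, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, roots.size + 1)
    labels[occupied] = rank[inverse]
    return labels.reshape(shape), int(roots.size)


def filter_small_clusters(clusters: np.ndarray,
                          min_voxels: int = MIN_CLUSTER_VOXELS
                          ) -> tuple[np.ndarray, int]:
    """Drop clusters below ``min_voxels`` and relabel densely by size."""
    out = clusters.copy()
    ids, counts = np.unique(out[out > 0], return_counts=True)
    for cid, cnt in zip(ids, counts):
        if cnt < min_voxels:
            out[out == cid] = 0
    keep_ids = np.unique(out[out > 0])
    relabeled = np.zeros_like(out)
    for new_id, cid in enumerate(keep_ids, start=1):
        relabeled[out == cid] = new_id
    return relabeled, int(keep_ids.size)


def classify_and_size(
    clusters: Volume3D,
    kinds: dict[int, str],
    spacing: tuple[float, float, float] | None = None,
) -> list[TumorRecord]:
    """Build :class:`TumorRecord` objects and assign relative size classes.

    Among tumors of the same kind in one exam, size classes XS < S < M < L
    < XL are assigned by ascending voxel count; a kind with a single tumor
    gets no size class.
    """
    spacing = spacing or clusters.spacing
    sx, sy, sz = spacing
    voxel_volume = sx * sy * sz
    data = clusters.data
    ids = [int(i) for i in np.unique(data) if i > 0]
    missing = [i for i in ids if i not in kinds]
    if missing:
        raise MetadataError(f"no benign/malignant kind given for clusters {missing}")

    nx_mid = data.shape[2] / 2.0
    records: list[TumorRecord] = []
    for cid in ids:
        sel = data == cid
        count = int(sel.sum())
        zc, yc, xc = (float(c) for c in np.argwhere(sel).mean(axis=0))
        ox, oy, oz = clusters.origin
        records.append(
            TumorRecord(
                cluster_id=cid,
                kind=kinds[cid],
                voxel_count=count,
                equivalent_diameter_cm=equivalent_diameter_cm(count, voxel_volume),
                centroid_mm=(ox + xc * sx, oy + yc * sy, oz + zc * sz),
                laterality="left" if xc < nx_mid else "right",
            )
        )

    for kind in ("benign", "malignant"):
        group = sorted(
            (r for r in records if r.kind == kind), key=lambda r: r.voxel_count
        )
        if len(group) < 2:
            continue
        if len(group) > len(SIZE_CLASSES):
            raise MetadataError(
                f"more than {len(SIZE_CLASSES)} {kind} tumors in one exam; "
                "relative size classes are undefined"
            )
        for cls, rec in zip(SIZE_CLASSES, group):
            rec.size_class = cls
    return records


def overlay_tumors(
    labels: Volume3D,
    records: list[TumorRecord],
    clusters: Volume3D,
    breast_region: np.ndarray | None = None,
) -> Volume3D:
    """Overwrite anatomy labels with tumor codes (benign -4, malignant -3)."""
    if labels.shape != clusters.shape:
        raise ParameterError("cluster volume does not align with the label map")
    out = labels.data.copy()
    kind_code = {"benign": -4, "malignant": -3}
    for rec in records:
        sel = clusters.data == rec.cluster_id
        if breast_region is not None and np.any(sel & ~breast_region.astype(bool)):
            warnings.warn(
                f"tumor cluster {rec.cluster_id} extends outside the breast region"
            )
        out[sel] = kind_code[rec.kind]
    return labels.with_data(out.astype(np.int16))


def propose_seeds(
    subtraction: Volume3D,
    breast_region: np.ndarray,
    threshold: float = 0.6,
) -> list[tuple[int, int, int]]:
    """Propose one seed per connected enhancing blob (> threshold) inside
    the breast region: the blob's brightest voxel."""
    cand = (subtraction.data > threshold) & breast_region.astype(bool)
    lab, n = ndimage.label(cand)
    seeds = []
    for i in range(1, n + 1):
        sel = np.argwhere(lab == i)
        vals = subtraction.data[tuple(sel.T)]
        z, y, x = sel[int(np.argmax(vals))]
        seeds.append((int(z), int(y), int(x)))
    return seeds


def match_kinds(
    clusters: Volume3D,
    kind_points: list[tuple[tuple[int, int, int], str]],
) -> dict[int, str]:
    """Assign each cluster the kind of the nearest annotated point (voxel
    index, kind); used to carry radiological benign/malignant labels into
    the segmentation."""
    data = clusters.data
    ids = [int(i) for i in np.unique(data) if i > 0]
    kinds: dict[int, str] = {}
    for cid in ids:
        centroid = np.argwhere(data == cid).mean(axis=0)
        best, best_d = None, np.inf
        for point, kind in kind_points:
            d = float(np.linalg.norm(centroid - np.asarray(point, dtype=float)))
            if d < best_d:
                best, best_d = kind, d
        if best is None:
            raise MetadataError("no annotated tumor kinds supplied")
        kinds[cid] = best
    return kinds


def records_to_csv(records: list[TumorRecord], path) -> None:
    """Write tumor metadata to a sidecar CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["cluster_id", "kind", "voxel_count", "equivalent_diameter_cm",
             "size_class", "laterality",
             "centroid_x_mm", "centroid_y_mm", "centroid_z_mm"]
        )
        for r in records:
            writer.writerow(
                [r.cluster_id, r.kind, r.voxel_count,
                 f"{r.equivalent_diameter_cm:.4f}",
                 r.size_class or "", r.laterality,
                 f"{r.centroid_mm[0]:.3f}", f"{r.centroid_mm[1]:.3f}",
                 f"{r.centroid_mm[2]:.3f}"]
            )


def read_kind_points_csv(path) -> list[tuple[tuple[int, int, int], str]]:
    """Read (voxel index, kind) annotations from a truth/annotation CSV with
    columns kind, seed_z, seed_y, seed_x."""
    points = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            points.append(
                ((int(row["seed_z"]), int(row["seed_y"]), int(row["seed_x"])),
                 row["kind"])
            )
    return points
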