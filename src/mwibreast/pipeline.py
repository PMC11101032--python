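"""End-to-end orchestration: channels in, label maps and tumor records out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import AnatomyConfig, segment_anatomy
from .preprocess import PreprocessConfig, run_preprocess
from .tumors import (
    MIN_CLUSTER_VOXELS,
    classify_and_size,
    filter_small_clusters,
    grow_tumor_candidates,
    hoshen_kopelman_label,
    match_kinds,
    overlay_tumors,
    propose_seeds,
)
from .volume import ExamBundle, Volume3D, simple_from_detailed


@dataclass
class SegmentationResult:
    detailed: Volume3D
    simple: Volume3D
    records: list
    clusters: Volume3D
    anatomy: dict


@dataclass
class TumorSegConfig:
    tol: float = 0.15
    seed_threshold: float = 0.6
    min_cluster_voxels: int = MIN_CLUSTER_VOXELS


def segment_exam(
    exam: ExamBundle,
    tumor_kind_points: list[tuple[tuple[int, int, int], str]] | None = None,
    preprocess_config: PreprocessConfig | None = None,
    anatomy_config: AnatomyConfig | None = None,
    tumor_config: TumorSegConfig | None = None,
    has_infracentimetric_tumor: bool = False,
) -> SegmentationResult:
    """Run pre-processing, anatomy segmentation and tumor segmentation.

    ``tumor_kind_points`` carries the radiological benign/malignant
    annotations as (voxel index, kind) pairs; the points also serve as
    growing seeds.  When omitted, seeds are auto-proposed from enhancing
    blobs of the subtraction channel and an exam is assumed tumor-free if
    none enhance.
    """
    tumor_config = tumor_config or TumorSegConfig()
    pre = run_preprocess(exam, preprocess_config, has_infracentimetric_tumor)
    anat = segment_anatomy(pre, anatomy_config)
    region = anat["breast_region"]

    seeds = [p for p, _ in tumor_kind_points] if tumor_kind_points else None
    if seeds is None:
        seeds = propose_seeds(pre.subtraction, region, tumor_config.seed_threshold)
    else:
        # keep only annotations that landed inside the segmented region
        seeds = [s for s in seeds if region[s]]

    labels = anat["labels"]
    if seeds:
        mask = grow_tumor_candidates(pre.subtraction, region, seeds,
                                     tumor_config.tol)
        clusters_arr, _ = hoshen_kopelman_label(mask)
        clusters_arr, n = filter_small_clusters(
            clusters_arr, tumor_config.min_cluster_voxels
        )
        clusters = labels.with_data(clusters_arr.astype(np.int16))
        if n and tumor_kind_points:
            kinds = match_kinds(clusters, tumor_kind_points)
        elif n:
            # without annotations, enhancing lesions default to malignant
            kinds = {cid: "malignant" for cid in range(1, n + 1)}
        else:
            kinds = {}
        records = classify_and_size(clusters, kinds) if kinds else []
        detailed = overlay_tumors(labels, records, clusters, region)
    else:
        clusters = labels.with_data(np.zeros(labels.shape, dtype=np.int16))
        records = []
        detailed = labels

    return SegmentationResult(
        detailed=detailed,
        simple=simple_from_detailed(detailed),
        records=records,
        clusters=clusters,
        anatomy=anat,
    )
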