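"""Shared fixtures: phantom exams and their segmentations.

The heavy end-to-end segmentations are session-scoped so the recovery,
vocabulary and acceptance tests share one run per study condition.
"""

from __future__ import annotations

import numpy as np
import pytest

from mwibreast.phantom import PhantomSpec, generate_phantom
from mwibreast.pipeline import segment_exam


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    s = int(a.sum()) + int(b.sum())
    return 2.0 * int((a & b).sum()) / s if s else 1.0


def truth_kind_points(truth, records):
    """(centroid voxel, kind) annotations derived from the ground truth."""
    points = []
    for rec in records:
        code = -3 if rec.kind == "malignant" else -4
        sel = np.argwhere(truth.data == code)
        # records of one kind may repeat; centroid of the matching cluster
        sx, sy, sz = truth.spacing
        cz = int(round(rec.centroid_mm[2] / sz))
        cy = int(round(rec.centroid_mm[1] / sy))
        cx = int(round(rec.centroid_mm[0] / sx))
        del sel
        points.append(((cz, cy, cx), rec.kind))
    return points


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(noise_sd=0.0, bias_amplitude=0.0, seed=0)
    exam, truth, records = generate_phantom(spec)
    return spec, exam, truth, records


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(noise_sd=0.05, bias_amplitude=0.2, seed=0)
    exam, truth, records = generate_phantom(spec)
    return spec, exam, truth, records


@pytest.fixture(scope="session")
def noiseless_segmentation(noiseless_phantom):
    _, exam, truth, records = noiseless_phantom
    result = segment_exam(exam, truth_kind_points(truth, records))
    return truth, records, result


@pytest.fixture(scope="session")
def noisy_segmentation(noisy_phantom):
    _, exam, truth, records = noisy_phantom
    result = segment_exam(exam, truth_kind_points(truth, records))
    return truth, records, result
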