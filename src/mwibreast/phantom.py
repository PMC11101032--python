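"""Synthetic exam generator: prone-geometry breast phantoms with ground truth.

The phantom emulates the content of a bilateral prone breast MRI exam on the
grid the segmentation pipeline expects: two half-ellipsoid breasts hanging
anterior of a chest-wall muscle slab, wrapped in a thin skin shell, with a
fibroglandular core carved from a thresholded smooth random field and
spherical tumors with Gaussian-perturbed radii.  Four co-registered channels
are emitted with per-tissue intensities — fat bright on the fat-only
channel, water-rich tissues bright on the water-only and in-phase channels,
tumors bright only on the contrast subtraction channel — modulated by a
smooth multiplicative bias field and additive Gaussian noise.  Water-only
intensities increase with tissue water content, matching the assumption the
dielectric mapping relies on.

All randomness flows from one integer seed through named `SeedSequence`
spawns, so outputs are bitwise reproducible and sub-generators are
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import preprocess
from .errors import ParameterError, PlacementError
from .tumors import TumorRecord, classify_and_size
from .volume import ExamBundle, Volume3D, simple_from_detailed

#: per-tissue channel intensity means (I, F, W, subtraction), arbitrary
#: scanner units in [0, 1]; W ordering encodes water content
TISSUE_INTENSITIES: dict[str, tuple[float, float, float, float]] = {
    "air": (0.0, 0.0, 0.0, 0.0),
    "thorax_tissue": (0.45, 0.10, 0.60, 0.03),
    "thoracic_fat": (0.75, 0.85, 0.15, 0.03),
    "muscle": (0.45, 0.08, 0.75, 0.03),
    "skin": (0.50, 0.30, 0.35, 0.03),
    "fibroglandular_low": (0.28, 0.10, 0.60, 0.03),
    "fibroglandular_median": (0.33, 0.10, 0.70, 0.03),
    "fibroglandular_high": (0.38, 0.10, 0.80, 0.03),
    "fat_low": (0.70, 0.82, 0.10, 0.03),
    "fat_median": (0.76, 0.85, 0.15, 0.03),
    "fat_high": (0.82, 0.88, 0.20, 0.03),
    "benign_tumor": (0.35, 0.10, 0.70, 0.80),
    "malignant_tumor": (0.35, 0.10, 0.75, 0.85),
}

_LABEL_OF_TISSUE = {
    "muscle": -1,
    "skin": -2,
    "fibroglandular_low": 1,
    "fibroglandular_median": 2,
    "fibroglandular_high": 3,
    "fat_low": 5,
    "fat_median": 6,
    "fat_high": 7,
    "benign_tumor": -4,
    "malignant_tumor": -3,
}


@dataclass(frozen=True)
class TumorSpec:
    """One synthetic tumor: kind, size, placement and shape irregularity."""

    kind: str                       # "benign" | "malignant"
    diameter_cm: float              # in [0.5, 8]
    center: tuple[int, int, int]    # (z, y, x) voxel index
    irregularity: float = 0.3       # in [0, 1]; scales radius perturbation

    def __post_init__(self) -> None:
        if self.kind not in ("benign", "malignant"):
            raise ParameterError(f"unknown tumor kind {self.kind!r}")
        if not 0.5 <= self.diameter_cm <= 8.0:
            raise ParameterError("tumor diameter must lie in [0.5, 8] cm")
        if not 0.0 <= self.irregularity <= 1.0:
            raise ParameterError("irregularity must lie in [0, 1]")


@dataclass
class PhantomSpec:
    """Study conditions of one synthetic exam.

    The defaults describe a bilateral prone exam on the repository grid
    (0.9965 x 0.9965 x 1 mm voxels) with one malignant and one benign tumor
    in the left breast and a healthy right breast, 25% fibroglandular
    fraction, a 20% smooth bias field and 5% additive noise.
    """

    shape: tuple[int, int, int] = (64, 128, 128)      # (z, y, x)
    spacing: tuple[float, float, float] = (0.9965, 0.9965, 1.0)
    chest_wall_y: int = 100
    muscle_thickness_vox: int = 18
    breast_semiaxes_mm: tuple[float, float, float] = (26.0, 80.0, 26.0)  # (z, y, x)
    breast_centers_x: tuple[int, int] = (34, 94)
    breast_center_z: int = 32
    skin_thickness_mm: float = 2.0
    subcutaneous_fat_mm: float = 3.0   # fat layer between skin and gland
    retromammary_fat_mm: float = 4.0   # fat space between gland and muscle
    fibro_fraction: float = 0.25
    fibro_smoothness_vox: float = 4.0
    tumors: tuple[TumorSpec, ...] = (
        TumorSpec("malignant", 2.0, (32, 64, 36)),
        TumorSpec("benign", 1.2, (32, 40, 30)),
    )
    intensities: dict = field(default_factory=lambda: dict(TISSUE_INTENSITIES))
    tissue_sd: float = 0.0          # smooth within-tissue heterogeneity
    bias_amplitude: float = 0.2
    noise_sd: float = 0.05
    seed: int = 0


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    """Normalized squared radial distance field of an axis-aligned ellipsoid."""
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape),
                             indexing="ij")
    cz, cy, cx = center
    az, ay, ax = semiaxes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance low-pass-filtered Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _tertile_split(field_values: np.ndarray) -> np.ndarray:
    """0/1/2 tertile index of each value (low water -> 0)."""
    q1, q2 = np.quantile(field_values, [1 / 3, 2 / 3])
    out = np.full(field_values.shape, 2, dtype=np.int8)
    out[field_values <= q2] = 1
    out[field_values <= q1] = 0
    return out


def generate_phantom(spec: PhantomSpec | None = None):
    """Build one synthetic exam.

    Returns ``(exam, labels, records)``: the raw co-registered channels, the
    ground-truth detailed-dialect label volume, and per-tumor metadata with
    relative size classes.
    """
    spec = spec or PhantomSpec()
    shape = tuple(spec.shape)
    nz, ny, nx = shape
    sx, sy, sz_mm = spec.spacing
    yc = spec.chest_wall_y

    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("fibro", "fat_subclass", "tumor", "bias", "noise", "tissue"),
            np.random.SeedSequence(spec.seed).spawn(6),
        )
    }

    # voxel semi-axes of the outer (skin-covered) breast surface
    az = spec.breast_semiaxes_mm[0] / sz_mm
    ay = spec.breast_semiaxes_mm[1] / sy
    ax = spec.breast_semiaxes_mm[2] / sx
    skin_vox = spec.skin_thickness_mm / sx

    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape),
                             indexing="ij")
    anterior = yy < yc  # breast side of the chest wall

    outer = np.zeros(shape, dtype=bool)
    base_foot = np.zeros((nz, nx), dtype=bool)
    for cx0 in spec.breast_centers_x:
        center = (spec.breast_center_z, yc, cx0)
        outer |= (_ellipsoid(shape, center, (az, ay, ax)) <= 1.0) & anterior
        # pectoral footprint: outer base ellipse grown by 2 voxels
        z2, x2 = np.meshgrid(np.arange(nz), np.arange(nx), indexing="ij")
        base_foot |= (
            ((z2 - spec.breast_center_z) / (az + 2)) ** 2
            + ((x2 - cx0) / (ax + 2)) ** 2
        ) <= 1.0

    # body envelope of chest and thorax
    chest_cols = np.zeros((nz, nx), dtype=bool)
    chest_cols[2: nz - 2, 4: nx - 4] = True
    slab = chest_cols[:, None, :] & (yy >= yc) & (yy < yc + spec.muscle_thickness_vox)
    thorax = chest_cols[:, None, :] & (yy >= yc + spec.muscle_thickness_vox)
    chest_skin = (
        chest_cols[:, None, :] & (yy >= yc - 2) & (yy < yc) & ~outer
    )

    # the skin shell is the set of breast voxels within the skin thickness
    # of the exterior (Euclidean distance in mm)
    body_all = outer | slab | thorax | chest_skin
    dist_air = ndimage.distance_transform_edt(body_all, sampling=(sz_mm, sy, sx))
    inner = outer & (dist_air > spec.skin_thickness_mm)

    tissue = np.zeros(shape, dtype=np.int8)  # indices into a tissue name list
    names = list(TISSUE_INTENSITIES)
    code = {name: i for i, name in enumerate(names)}

    tissue[thorax] = code["thorax_tissue"]
    # thoracic fat pockets, separated from breast fat by the muscle slab
    for cx0 in spec.breast_centers_x:
        pocket = _ellipsoid(
            shape, (spec.breast_center_z, yc + spec.muscle_thickness_vox + 4, cx0),
            (10, 4, 14),
        ) <= 1.0
        tissue[pocket & thorax] = code["thoracic_fat"]
    tissue[slab] = code["muscle"]
    tissue[chest_skin] = code["skin"]
    tissue[outer & ~inner] = code["skin"]

    # fibroglandular core from a thresholded smooth field.  The gland is
    # confined to a core region separated from the skin by a subcutaneous
    # fat layer and from the pectoral muscle by the retromammary fat space,
    # as in real breast anatomy.
    sub_fat = spec.subcutaneous_fat_mm / sx
    gland = np.zeros(shape, dtype=bool)
    for cx0 in spec.breast_centers_x:
        center = (spec.breast_center_z, yc, cx0)
        semi = (az - skin_vox - sub_fat, ay - skin_vox - sub_fat,
                ax - skin_vox - sub_fat)
        gland |= (_ellipsoid(shape, center, semi) <= 1.0) & (
            yy <= yc - spec.retromammary_fat_mm / sy
        )
    gland &= inner
    fibro_field = _smooth_field(streams["fibro"], shape, spec.fibro_smoothness_vox)
    # quantile chosen so the gland occupies fibro_fraction of the interior
    n_target = spec.fibro_fraction * int(inner.sum())
    q = max(0.0, 1.0 - n_target / max(int(gland.sum()), 1))
    thr = np.quantile(fibro_field[gland], q)
    fibro = gland & (fibro_field > thr)
    fat = inner & ~fibro

    fib_sub = _tertile_split(fibro_field[fibro])  # higher field = more water
    fib_names = ["fibroglandular_low", "fibroglandular_median", "fibroglandular_high"]
    sub_codes = np.array([code[n] for n in fib_names], dtype=np.int8)
    tissue[fibro] = sub_codes[fib_sub]

    fat_field = _smooth_field(streams["fat_subclass"], shape,
                              spec.fibro_smoothness_vox)
    fat_sub = _tertile_split(fat_field[fat])
    fat_names = ["fat_low", "fat_median", "fat_high"]
    sub_codes = np.array([code[n] for n in fat_names], dtype=np.int8)
    tissue[fat] = sub_codes[fat_sub]

    # tumors: perturbed spheres, confined to the breast interior
    tumor_clusters = np.zeros(shape, dtype=np.int16)
    tumor_masks = []
    for t in spec.tumors:
        r_mm = t.diameter_cm * 10.0 / 2.0
        radii = (r_mm / sz_mm, r_mm / sy, r_mm / sx)
        dist = np.sqrt(_ellipsoid(shape, t.center, radii))
        pert = _smooth_field(streams["tumor"], shape, 3.0)
        mask = dist <= 1.0 + 0.3 * t.irregularity * pert
        if not mask.any():
            raise PlacementError(f"tumor at {t.center} produced no voxels")
        if np.any(mask & ~inner):
            raise PlacementError(
                f"tumor at {t.center} (d={t.diameter_cm} cm) does not fit "
                "inside the breast interior"
            )
        if any(np.any(mask & m) for m in tumor_masks):
            raise PlacementError(f"tumor at {t.center} overlaps another tumor")
        tumor_masks.append(mask)
        tissue[mask] = code[f"{t.kind}_tumor"]

    # cluster ids in descending voxel-count order, as the labeling convention
    order = sorted(
        range(len(tumor_masks)), key=lambda i: -int(tumor_masks[i].sum())
    )
    kinds: dict[int, str] = {}
    for cid, i in enumerate(order, start=1):
        tumor_clusters[tumor_masks[i]] = cid
        kinds[cid] = spec.tumors[i].kind

    # ground-truth detailed label map
    labels = np.zeros(shape, dtype=np.int16)
    muscle_truth = slab & base_foot[:, None, :]
    labels[muscle_truth] = -1
    for name, lab in _LABEL_OF_TISSUE.items():
        if name == "muscle":
            continue
        labels[tissue == code[name]] = lab

    # render channels
    means = np.array(
        [spec.intensities[n] for n in names], dtype=np.float64
    )  # (n_tissues, 4 channels)
    channels = means[tissue]  # (z, y, x, 4)

    if spec.tissue_sd > 0:
        het = _smooth_field(streams["tissue"], shape, 6.0)
        channels = channels * (1.0 + spec.tissue_sd * het[..., None])

    if spec.bias_amplitude > 0:
        g = _smooth_field(streams["bias"], shape, 24.0)
        g = g / max(np.abs(g).max(), 1e-12)
        channels = channels * (1.0 + spec.bias_amplitude * g)[..., None]

    if spec.noise_sd > 0:
        channels = channels + streams["noise"].normal(
            0.0, spec.noise_sd, size=channels.shape
        )
        channels = np.clip(channels, 0.0, None)

    def _vol(idx: int) -> Volume3D:
        return Volume3D(channels[..., idx].astype(np.float32), spec.spacing)

    exam = ExamBundle(
        I=_vol(0), F=_vol(1), W=_vol(2), subtraction=_vol(3),
        metadata={"phantom_seed": spec.seed},
    )
    label_vol = Volume3D(labels, spec.spacing)
    clusters_vol = Volume3D(tumor_clusters, spec.spacing)
    records = classify_and_size(clusters_vol, kinds) if kinds else []
    return exam, label_vol, records


# ---------------------------------------------------------------------------
# scenario presets mirroring the variety of the patient repository

_LEFT, _RIGHT = (32, 60, 34), (32, 60, 94)


def preset(name: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Named phantom scenarios: tumor-free, single benign, single malignant,
    bilateral benign, and a malignant+benign breast with a healthy
    contralateral breast ("exam4-like")."""
    presets: dict[str, tuple[TumorSpec, ...]] = {
        "tumor_free": (),
        "single_benign": (TumorSpec("benign", 2.0, _LEFT),),
        "single_malignant": (TumorSpec("malignant", 2.0, _LEFT),),
        "multi_benign_bilateral": (
            TumorSpec("benign", 1.5, _LEFT),
            TumorSpec("benign", 2.5, _RIGHT),
        ),
        "exam4_like": (
            TumorSpec("malignant", 2.0, (32, 64, 36)),
            TumorSpec("benign", 1.2, (32, 40, 30)),
        ),
    }
    if name not in presets:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        )
    return PhantomSpec(tumors=presets[name], seed=seed, **overrides)


def has_infracentimetric_tumor(spec: PhantomSpec) -> bool:
    return any(t.diameter_cm < 1.0 for t in spec.tumors)


def write_exam_folder(spec: PhantomSpec, outdir: str | Path,
                      compressed: bool = False) -> Path:
    """Generate a phantom and write it in the per-patient folder layout.

    The folder holds the pre-processed water-only channel, both label-map
    dialects, the raw channels under ``channels/`` and a tumor truth CSV
    (kind, seed voxel, size) usable as segmentation annotations.
    """
    from .mha_io import write_mha  # local import to avoid cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exam, labels, records = generate_phantom(spec)

    cfg = preprocess.PreprocessConfig()
    w_pre = preprocess.correct_bias_field(exam.W, cfg)
    w_pre = preprocess.minmax_normalize(w_pre)
    if not has_infracentimetric_tumor(spec):
        w_pre = preprocess.median_filter(w_pre, cfg.median_kernel_radius)

    write_mha(w_pre.with_data(w_pre.data.astype(np.float32)),
              outdir / "T1w_Dixon_W.mha", compressed)
    write_mha(labels, outdir / "Label_map_detailed.mha", compressed)
    write_mha(simple_from_detailed(labels), outdir / "Label_map_simple.mha",
              compressed)

    chan_dir = outdir / "channels"
    chan_dir.mkdir(exist_ok=True)
    for name, vol in exam.channels.items():
        write_mha(vol, chan_dir / f"{name}.mha", compressed)

    _write_truth_csv(records, labels, outdir / "tumors_truth.csv")
    return outdir


def _write_truth_csv(records: list[TumorRecord], labels: Volume3D, path) -> None:
    import csv

    sx, sy, sz = labels.spacing
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["kind", "seed_z", "seed_y", "seed_x", "voxel_count",
             "equivalent_diameter_cm", "size_class", "laterality"]
        )
        for r in records:
            xc, yc_mm, zc = r.centroid_mm
            writer.writerow(
                [r.kind, int(round(zc / sz)), int(round(yc_mm / sy)),
                 int(round(xc / sx)), r.voxel_count,
                 f"{r.equivalent_diameter_cm:.4f}", r.size_class or "",
                 r.laterality]
            )
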