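"""Anatomy segmentation: breast-region extraction, skin/muscle shells and
Gaussian-mixture fat/fibroglandular classification.

The chain mirrors the standard prone-breast processing recipe:

1. estimate a sternum seed on the anterior chest-wall midline from the
   water-only channel;
2. grow breast fat on the fat-only channel (running-mean region growing,
   6-connectivity) so thoracic fat, separated by the chest-wall muscle, is
   excluded;
3. dilate the fat mask (ball, radius 3) and fill each anterior column of the
   body down to the posterior-most dilated-fat voxel, yielding the breast
   region (fat + fibroglandular + skin);
4. carve skin (air-adjacent shell) and muscle (posterior shell) masks;
5. fit a two-component Gaussian mixture to in-phase intensities of the
   breast interior (fat is T1-bright), subdivide each class into
   low/median/high intensity tertiles, and flag low-confidence voxels as
   transition tissue.

Axis convention: arrays are (z, y, x) with y increasing anterior -> posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from ._grow import region_grow
from .errors import (
    EmptyRegionError,
    InsufficientDataError,
    ParameterError,
    SeedNotFoundError,
)
from .volume import Volume3D


@dataclass
class AnatomyConfig:
    """Tunables of the anatomy chain (all lengths in voxels)."""

    fat_tol: float = 0.15              # region-growing tolerance, normalized units
    dilation_radius: int = 3           # fat-mask dilation before column fill
    skin_thickness: int = 2            # ~2 mm at the default spacing
    muscle_thickness: int = 15
    body_threshold: float = 0.15       # in-phase threshold for the body mask
    transition_posterior: float = 0.9  # below this max posterior -> transition
    gmm_seed: int = 0


@dataclass
class GmmFit:
    """Two-component univariate Gaussian mixture over in-phase intensities."""

    means: tuple[float, float]        # (mu_fat, mu_fib), fat is the brighter
    variances: tuple[float, float]
    weights: tuple[float, float]
    posterior_threshold_transition: float = 0.9

    def __post_init__(self) -> None:
        if not all(v > 0 for v in self.variances):
            raise ParameterError("GMM variances must be strictly positive")
        w = self.weights
        if not (abs(w[0] + w[1] - 1.0) < 1e-6 and 0 < w[0] < 1 and 0 < w[1] < 1):
            raise ParameterError("GMM weights must be in (0,1) and sum to 1")

    def posteriors(self, values: np.ndarray) -> np.ndarray:
        """Column-stacked posteriors (fat, fib) for each value."""
        v = np.asarray(values, dtype=np.float64)[:, None]
        mu = np.asarray(self.means)[None, :]
        var = np.asarray(self.variances)[None, :]
        w = np.asarray(self.weights)[None, :]
        log_p = (
            np.log(w) - 0.5 * np.log(2 * np.pi * var) - (v - mu) ** 2 / (2 * var)
        )
        log_p -= log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p)
        return p / p.sum(axis=1, keepdims=True)


def estimate_sternum_seed(W: Volume3D, threshold: float = 0.5,
                          run_length: int = 3) -> tuple[int, int, int]:
    """Locate the anterior chest wall on the mid-sagittal midline.

    Scans the mid-sagittal column of the central axial slice from anterior
    to posterior and returns the first voxel starting a sustained run
    (length >= ``run_length``) of water-bright intensities above
    ``threshold``.  The water-rich chest-wall muscle produces this run.
    """
    nz, ny, nx = W.shape
    z_mid, x_mid = nz // 2, nx // 2
    column = W.data[z_mid, :, x_mid]
    above = column > threshold
    for y in range(ny - run_length + 1):
        if above[y: y + run_length].all():
            return (z_mid, y, x_mid)
    raise SeedNotFoundError(
        "no sustained water-bright run on the mid-sagittal midline "
        f"(threshold {threshold}, run length {run_length}); "
        f"column max = {column.max():.3f}"
    )


def grow_breast_fat(F: Volume3D, seed: tuple[int, int, int],
                    intensity_tol: float = 0.15) -> np.ndarray:
    """6-connected running-mean region growing on the fat-only channel.

    Growth halts where fat intensity drops (chest wall, skin, fibroglandular
    tissue).  A seed on a background voxel raises
    :class:`EmptyRegionError`.
    """
    z, y, x = seed
    nz, ny, nx = F.shape
    if not (0 <= z < nz and 0 <= y < ny and 0 <= x < nx):
        raise EmptyRegionError(f"seed {seed} outside volume {F.shape}")
    if F.data[z, y, x] <= 0.05:
        raise EmptyRegionError(
            f"seed {seed} lies on a background voxel "
            f"(F = {float(F.data[z, y, x]):.3f})"
        )
    return region_grow(F.data.astype(np.float64), [seed], intensity_tol)


def dilate_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological dilation with a Euclidean ball of the given radius.

    Implemented via the exact Euclidean distance transform (a voxel is set
    when its distance to the mask is <= radius), which is equivalent to
    dilation with the discretized ball and fast for large radii.
    """
    if radius < 1:
        raise ParameterError("dilation radius must be >= 1")
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask.astype(bool))
    return dist <= radius


def build_breast_region(fat_mask: np.ndarray, body_mask: np.ndarray,
                        dilation_radius: int = 3) -> np.ndarray:
    """Dilate the fat mask and whiten out the anterior body.

    For each (z, x) column, all body voxels anterior to (and including) the
    posterior-most dilated-fat voxel are added, so skin and enclosed
    fibroglandular tissue join the mask.
    """
    if not fat_mask.any():
        warnings.warn("empty fat mask: breast region is empty")
        return np.zeros_like(fat_mask, dtype=bool)
    dilated = dilate_mask(fat_mask, dilation_radius)
    # posterior-most dilated-fat index per (z, x) column; -1 where none
    ny = fat_mask.shape[1]
    y_idx = np.arange(ny)[None, :, None]
    y_post = np.max(np.where(dilated, y_idx, -1), axis=1)  # (nz, nx)
    fill = y_idx <= y_post[:, None, :]
    return fill & body_mask.astype(bool)


def extract_skin_muscle(
    breast_region: np.ndarray,
    body_mask: np.ndarray,
    skin_thickness: int = 2,
    muscle_thickness: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Carve the skin and muscle shells from the breast region.

    Skin is the air-adjacent shell of the breast region (voxels within
    ``skin_thickness`` of non-body space); muscle is the posterior shell of
    thickness ``muscle_thickness`` directly behind the breast region, inside
    the body.  The two masks are disjoint by construction.
    """
    if skin_thickness < 1 or muscle_thickness < 1:
        raise ParameterError("shell thicknesses must be >= 1 voxel")
    breast_region = breast_region.astype(bool)
    body_mask = body_mask.astype(bool)
    if not breast_region.any():
        empty = np.zeros_like(breast_region)
        return empty, empty.copy()

    dist_to_air = ndimage.distance_transform_edt(body_mask)
    skin = breast_region & (dist_to_air <= skin_thickness)

    # columns posterior of any breast-region voxel
    behind = np.maximum.accumulate(breast_region, axis=1)
    dist_to_region = ndimage.distance_transform_edt(~breast_region)
    muscle = (
        body_mask
        & ~breast_region
        & behind
        & (dist_to_region <= muscle_thickness)
        & ~skin
    )
    return skin, muscle


def compute_body_mask(I: Volume3D, threshold: float = 0.15) -> np.ndarray:
    """Threshold the in-phase channel, keep the largest component and fill
    holes slice-wise; the result is the body envelope."""
    raw = I.data > threshold
    if not raw.any():
        return raw
    lab, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, lab, index=np.arange(1, n + 1))
        raw = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(raw)


def fit_gmm_fat_fib(I: Volume3D, interior: np.ndarray,
                    seed: int = 0,
                    posterior_threshold_transition: float = 0.9) -> GmmFit:
    """Fit a two-component Gaussian mixture to interior in-phase intensities.

    EM with tolerance 1e-6 on the log-likelihood, at most 500 iterations and
    k-means++ initialization from a fixed seed.  The brighter component is
    fat (fat is T1-bright on in-phase images).
    """
    values = I.data[interior.astype(bool)].astype(np.float64)
    if values.size < 100:
        raise InsufficientDataError(
            f"only {values.size} interior voxels; need >= 100 for the GMM"
        )
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=1e-6,
        max_iter=500,
        init_params="k-means++",
        random_state=seed,
        reg_covar=1e-10,
    ).fit(values[:, None])
    means = gm.means_.ravel()
    variances = gm.covariances_.ravel()
    weights = gm.weights_.ravel()
    fat = int(np.argmax(means))  # brighter component on I = fat
    fib = 1 - fat
    return GmmFit(
        means=(float(means[fat]), float(means[fib])),
        variances=(float(variances[fat]), float(variances[fib])),
        weights=(float(weights[fat]), float(weights[fib])),
        posterior_threshold_transition=posterior_threshold_transition,
    )


def _tertile_labels(values: np.ndarray, base_low: int) -> np.ndarray:
    """Split values into low/median/high tertiles -> base_low, +1, +2."""
    out = np.full(values.shape, base_low + 2, dtype=np.int16)
    if values.size == 0:
        return out
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3])
    out[values <= q2] = base_low + 1
    out[values <= q1] = base_low
    return out


def classify_interior(I: Volume3D, interior: np.ndarray, fit: GmmFit) -> Volume3D:
    """Label interior voxels with the detailed-dialect codes 1-7.

    Fat vs fibroglandular by maximum posterior; voxels whose maximum
    posterior falls below the transition threshold get label 4; each class
    is then split into intensity tertiles (fibroglandular 1-3, fat 5-7).
    """
    interior = interior.astype(bool)
    labels = np.zeros(I.shape, dtype=np.int16)
    values = I.data[interior].astype(np.float64)
    if values.size == 0:
        return I.with_data(labels)
    post = fit.posteriors(values)  # columns (fat, fib)
    is_transition = post.max(axis=1) < fit.posterior_threshold_transition
    is_fat = (post[:, 0] >= post[:, 1]) & ~is_transition
    is_fib = ~is_fat & ~is_transition

    out = np.zeros(values.shape, dtype=np.int16)
    out[is_transition] = 4
    out[is_fib] = _tertile_labels(values[is_fib], 1)
    out[is_fat] = _tertile_labels(values[is_fat], 5)
    labels[interior] = out
    return I.with_data(labels)


def segment_anatomy(
    exam_preprocessed,
    config: AnatomyConfig | None = None,
) -> dict:
    """Run the full anatomy chain on a preprocessed exam.

    Returns a dict with the body mask, sternum seed, fat mask, breast
    region, skin/muscle masks, interior mask, the Gaussian-mixture fit and
    a detailed-dialect label volume (tumors not yet overlaid).
    """
    config = config or AnatomyConfig()
    W, F, I = exam_preprocessed.W, exam_preprocessed.F, exam_preprocessed.I

    body = compute_body_mask(I, config.body_threshold)
    sternum = estimate_sternum_seed(W)

    # one fat seed per lateral half: the brightest fat-only voxel anterior
    # of the chest wall, so each breast is grown even when the two fat
    # compartments are not connected across the midline
    nz, ny, nx = F.shape
    z_mid, y_chest, x_mid = sternum
    fat = np.zeros(F.shape, dtype=bool)
    for x_lo, x_hi in ((0, x_mid), (x_mid, nx)):
        sub = F.data[z_mid, : max(y_chest - 2, 1), x_lo:x_hi]
        if sub.size == 0 or sub.max() <= 0.05:
            continue
        y_s, x_s = np.unravel_index(int(np.argmax(sub)), sub.shape)
        fat |= grow_breast_fat(F, (z_mid, int(y_s), int(x_s + x_lo)),
                               config.fat_tol)
    if not fat.any():
        raise EmptyRegionError("no breast fat found anterior of the chest wall")

    region = build_breast_region(fat, body, config.dilation_radius)
    skin, muscle = extract_skin_muscle(
        region, body, config.skin_thickness, config.muscle_thickness
    )

    # the column fill is bounded by the *dilated* fat mask, so its last
    # ~dilation_radius layers carry no fat evidence; tissue posterior of the
    # undilated fat in a column is chest wall (behind the retromammary fat)
    # and is attributed to muscle rather than the breast interior
    y_axis = np.arange(F.shape[1])[None, :, None]
    y_fat_post = np.max(np.where(fat, y_axis, -1), axis=1)  # (nz, nx)
    has_fat_col = y_fat_post >= 0
    post_trim = (
        region
        & (y_axis > y_fat_post[:, None, :])
        & has_fat_col[:, None, :]
        & ~skin
    )
    muscle = muscle | post_trim
    interior = region & ~skin & ~post_trim

    fit = fit_gmm_fat_fib(
        I, interior, seed=config.gmm_seed,
        posterior_threshold_transition=config.transition_posterior,
    )
    interior_labels = classify_interior(I, interior, fit)

    labels = interior_labels.data.copy()
    labels[skin] = -2
    labels[muscle] = -1
    return {
        "body": body,
        "sternum_seed": sternum,
        "fat_mask": fat,
        "breast_region": region,
        "skin": skin,
        "muscle": muscle,
        "interior": interior,
        "gmm": fit,
        "labels": I.with_data(labels),
    }
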