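"""Pre-processing chain: bias-field correction, min-max normalization and
median filtering.

The chain runs in the fixed order bias -> normalize -> median.  Exams with
infra-centimetric tumors (diameter < 1 cm) skip the median filter on every
channel so that the smallest lesions are not eroded by the smoothing pass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import ParameterError
from .volume import ExamBundle, Volume3D, check_same_geometry

logger = logging.getLogger("mwibreast.preprocess")


@dataclass
class PreprocessConfig:
    """Tunables of the pre-processing chain.

    ``median_kernel_radius`` is in voxels (the kernel is the cubic
    ``(2r+1)^3`` neighborhood); ``bias_poly_order`` is the degree of the
    log-domain polynomial bias estimator; ``bias_method`` selects between
    the built-in polynomial estimator and SimpleITK's N4 corrector.
    """

    median_kernel_radius: int = 1
    apply_median: bool = True
    bias_poly_order: int = 3
    bias_method: str = "n4"  # or "polynomial"
    normalization: str = "minmax"

    def __post_init__(self) -> None:
        if self.median_kernel_radius < 1:
            raise ParameterError("median_kernel_radius must be >= 1")
        if not 1 <= self.bias_poly_order <= 4:
            raise ParameterError("bias_poly_order must be in [1, 4]")
        if self.bias_method not in ("polynomial", "n4"):
            raise ParameterError(f"unknown bias_method {self.bias_method!r}")
        if self.normalization != "minmax":
            raise ParameterError("only min-max normalization is supported")


def _foreground_mask(data: np.ndarray) -> np.ndarray:
    """Foreground = top 90% of the strictly positive intensities."""
    positive = data > 0
    if not positive.any():
        return positive
    cutoff = np.percentile(data[positive], 10.0)
    return data > cutoff


def _poly_design(coords: list[np.ndarray], order: int) -> np.ndarray:
    """Monomial design matrix z^a y^b x^c for all a+b+c <= order."""
    cols = []
    z, y, x = coords
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                cols.append((z ** a) * (y ** b) * (x ** c))
    return np.stack(cols, axis=-1)


def _polynomial_field(data: np.ndarray, fg: np.ndarray, order: int) -> np.ndarray:
    """Estimate a smooth multiplicative field as exp(polynomial fit of log I)."""
    shape = data.shape
    # normalized coordinates in [-1, 1] keep the design matrix conditioned
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")

    idx = np.flatnonzero(fg)
    rng = np.random.default_rng(0)  # deterministic subsample for the fit
    if idx.size > 50_000:
        idx = rng.choice(idx, size=50_000, replace=False)
    pts = [zz.ravel()[idx], yy.ravel()[idx], xx.ravel()[idx]]
    design = _poly_design(pts, order)
    logv = np.log(data.ravel()[idx])
    coef, *_ = np.linalg.lstsq(design, logv, rcond=None)

    log_field = np.zeros(shape, dtype=np.float64)
    k = 0
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                log_field += coef[k] * (zz ** a) * (yy ** b) * (xx ** c)
                k += 1
    # unit geometric mean over the foreground
    log_field -= log_field[fg].mean()
    return np.exp(log_field)


def _n4_field(data: np.ndarray, fg: np.ndarray) -> np.ndarray:
    """N4 bias estimation on a shrunken copy; the fitted B-spline field is
    sampled back at full resolution.

    N4's histogram-sharpening objective keeps anatomy-scale contrast out of
    the field, which a plain polynomial fit cannot guarantee on
    multi-tissue volumes.
    """
    img = sitk.GetImageFromArray(data.astype(np.float32))
    mask = sitk.GetImageFromArray(fg.astype(np.uint8))
    # estimate on a ~32-voxel-per-axis grid: the field is smooth by model
    shrink = [max(1, s // 32) for s in img.GetSize()]
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.SetMaximumNumberOfIterations([25, 25, 25])
    corrector.Execute(sitk.Shrink(img, shrink), sitk.Shrink(mask, shrink))
    log_field = sitk.GetArrayFromImage(
        corrector.GetLogBiasFieldAsImage(img)
    ).astype(np.float64)
    log_field -= log_field[fg].mean()
    return np.exp(log_field)


def correct_bias_field(vol: Volume3D, config: PreprocessConfig | None = None) -> Volume3D:
    """Divide out a smooth, strictly positive multiplicative intensity field.

    The field is estimated from the foreground (top 90% of positive voxels)
    and normalized to unit geometric mean over it; the output is rescaled so
    its foreground arithmetic mean matches the input's.  A constant volume is
    returned unchanged with a warning.
    """
    config = config or PreprocessConfig()
    data = vol.data.astype(np.float64)
    fg = _foreground_mask(data)
    if not fg.any() or np.ptp(data[fg]) == 0:
        warnings.warn("constant or empty foreground: bias correction skipped")
        return vol.with_data(data)
    if config.bias_method == "n4":
        field = _n4_field(data, fg)
    else:
        field = _polynomial_field(data, fg, config.bias_poly_order)
    out = data / field
    out *= data[fg].mean() / out[fg].mean()
    return vol.with_data(out)


def minmax_normalize(vol: Volume3D) -> Volume3D:
    """Affinely map intensities to [0, 1]; a constant volume maps to zeros."""
    data = vol.data.astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        warnings.warn("constant volume: min-max normalization returns zeros")
        return vol.with_data(np.zeros_like(data))
    return vol.with_data((data - lo) / (hi - lo))


def median_filter(vol: Volume3D, radius: int = 1) -> Volume3D:
    """Median over the cubic (2r+1)^3 neighborhood, edges replicated."""
    if radius < 1:
        raise ParameterError("median filter radius must be >= 1")
    out = ndimage.median_filter(
        vol.data.astype(np.float64), size=2 * radius + 1, mode="nearest"
    )
    return vol.with_data(out)


def run_preprocess(
    exam: ExamBundle,
    config: PreprocessConfig | None = None,
    has_infracentimetric_tumor: bool = False,
) -> ExamBundle:
    """Apply bias correction -> min-max normalization -> median filter to
    every channel.

    When ``has_infracentimetric_tumor`` is set (lesion under 1 cm present)
    the median filter is skipped on all channels to preserve lesion size and
    shape.
    """
    config = config or PreprocessConfig()
    check_same_geometry(exam.I, exam.F, exam.W, exam.subtraction)
    apply_median = config.apply_median and not has_infracentimetric_tumor
    processed: dict[str, Volume3D] = {}
    for name, chan in exam.channels.items():
        logger.info("channel %s: bias-field correction (%s, order %d)",
                    name, config.bias_method, config.bias_poly_order)
        out = correct_bias_field(chan, config)
        logger.info("channel %s: min-max normalization", name)
        out = minmax_normalize(out)
        if apply_median:
            logger.info("channel %s: median filter (radius %d)",
                        name, config.median_kernel_radius)
            out = median_filter(out, config.median_kernel_radius)
        else:
            logger.info("channel %s: median filter skipped", name)
        processed[name] = out
    return exam.replace_channels(**processed)
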