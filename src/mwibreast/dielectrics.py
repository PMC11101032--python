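"""Dispersion models and voxelwise dielectric property assignment.

Tissues are described by single-pole Debye or Cole-Cole dispersions

    eps*(w) = eps_inf + delta_eps / (1 + (j w tau)^(1-alpha)) + sigma_s / (j w eps0)

with relative permittivity ``eps_r = Re(eps*)`` and effective conductivity
``sigma_eff = -w eps0 Im(eps*)`` (alpha = 0 reduces Cole-Cole to Debye).
Voxel intensities of the water-only channel are mapped piecewise-linearly
onto per-tissue curve envelopes: skin and muscle use +/-5% heterogeneity
bands around their nominal curve, fat/fibroglandular subclasses use the
adjacent subclass curves as envelopes, benign tumors span the fibroglandular
envelope, and malignant tumors take the Cole-Cole curve converted to a
band-limited Debye equivalent.

Frequencies are restricted to the 3-10 GHz grid with 0.01 GHz spacing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, FrequencyGridError, ParameterError, TableError
from .mha_io import PropertyMaps
from .volume import DETAILED_LABELS, SIMPLE_LABELS, Volume3D, check_same_geometry

#: vacuum permittivity, F/m
EPS0 = 8.8541878128e-12

FREQ_MIN_GHZ = 3.0
FREQ_MAX_GHZ = 10.0
FREQ_STEP_GHZ = 0.01


@dataclass(frozen=True)
class DispersionParams:
    """Single-pole Debye or Cole-Cole dispersion parameters.

    ``tau`` is in seconds; ``sigma_s`` in S/m; ``alpha`` must be 0 for the
    Debye model.
    """

    model: str  # "debye" | "cole_cole"
    eps_inf: float
    delta_eps: float
    tau: float
    sigma_s: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("debye", "cole_cole"):
            raise ParameterError(f"unknown dispersion model {self.model!r}")
        if self.eps_inf < 1:
            raise ParameterError("eps_inf must be >= 1")
        if self.delta_eps < 0 or self.sigma_s < 0:
            raise ParameterError("delta_eps and sigma_s must be >= 0")
        if self.tau <= 0:
            raise ParameterError("tau must be > 0")
        if not 0 <= self.alpha < 1:
            raise ParameterError("alpha must be in [0, 1)")
        if self.model == "debye" and self.alpha != 0:
            raise ParameterError("Debye model requires alpha = 0")


def frequency_grid() -> np.ndarray:
    """All valid frequencies: 3.00, 3.01, ..., 10.00 GHz (701 values)."""
    n = int(round((FREQ_MAX_GHZ - FREQ_MIN_GHZ) / FREQ_STEP_GHZ)) + 1
    return np.round(FREQ_MIN_GHZ + FREQ_STEP_GHZ * np.arange(n), 10)


def validate_frequency(f_ghz: float) -> float:
    """Return ``f_ghz`` if it lies on the grid, else raise with the nearest
    valid values in the message."""
    k = (f_ghz - FREQ_MIN_GHZ) / FREQ_STEP_GHZ
    k_round = round(k)
    on_step = abs(f_ghz - (FREQ_MIN_GHZ + FREQ_STEP_GHZ * k_round)) <= 1e-9
    if FREQ_MIN_GHZ - 1e-9 <= f_ghz <= FREQ_MAX_GHZ + 1e-9 and on_step:
        return float(np.round(FREQ_MIN_GHZ + FREQ_STEP_GHZ * k_round, 10))
    lo = FREQ_MIN_GHZ + FREQ_STEP_GHZ * max(0, min(700, math.floor(k)))
    hi = FREQ_MIN_GHZ + FREQ_STEP_GHZ * max(0, min(700, math.ceil(k)))
    raise FrequencyGridError(
        f"{f_ghz} GHz is not on the 3-10 GHz grid with 0.01 GHz step; "
        f"nearest valid values: {lo:.2f}, {hi:.2f}"
    )


def _omega(f_ghz: float | np.ndarray) -> float | np.ndarray:
    return 2.0 * np.pi * np.asarray(f_ghz, dtype=np.float64) * 1e9


def debye_eval(p: DispersionParams, f_ghz: float | np.ndarray):
    """Evaluate a Debye dispersion; returns ``(eps_r, sigma_eff)``.

    Closed forms: with w = 2 pi f,
    eps_r = eps_inf + delta_eps / (1 + w^2 tau^2),
    sigma_eff = sigma_s + eps0 * delta_eps * w^2 * tau / (1 + w^2 tau^2).
    """
    if p.model != "debye":
        raise ParameterError("debye_eval requires a Debye parameter set")
    w = _omega(f_ghz)
    wt2 = (w * p.tau) ** 2
    eps_r = p.eps_inf + p.delta_eps / (1.0 + wt2)
    sigma = p.sigma_s + EPS0 * p.delta_eps * w ** 2 * p.tau / (1.0 + wt2)
    return eps_r, sigma


def cole_cole_eval(p: DispersionParams, f_ghz: float | np.ndarray):
    """Evaluate a Cole-Cole dispersion; returns ``(eps_r, sigma_eff)``."""
    if p.model != "cole_cole":
        raise ParameterError("cole_cole_eval requires a Cole-Cole parameter set")
    w = _omega(f_ghz)
    eps_c = (
        p.eps_inf
        + p.delta_eps / (1.0 + (1j * w * p.tau) ** (1.0 - p.alpha))
        + p.sigma_s / (1j * w * EPS0)
    )
    return np.real(eps_c), -w * EPS0 * np.imag(eps_c)


def eval_dispersion(p: DispersionParams, f_ghz: float | np.ndarray):
    return debye_eval(p, f_ghz) if p.model == "debye" else cole_cole_eval(p, f_ghz)


def cole_to_debye(p: DispersionParams, grid: np.ndarray | None = None) -> DispersionParams:
    """Fit a band-limited Debye equivalent to a Cole-Cole dispersion.

    Least-squares over the full frequency grid of squared relative errors in
    both eps_r and sigma_eff, initialized at the Cole-Cole parameter values.
    """
    if p.model != "cole_cole":
        raise ParameterError("cole_to_debye requires a Cole-Cole parameter set")
    freqs = frequency_grid() if grid is None else np.asarray(grid, dtype=float)
    eps_t, sig_t = cole_cole_eval(p, freqs)

    # tau is carried in picoseconds inside the optimizer so all four
    # parameters share a comparable scale (a tau in seconds makes the
    # finite-difference Jacobian column vanish in double precision)
    def residuals(x):
        q = DispersionParams("debye", x[0], x[1], x[2] * 1e-12, x[3])
        eps, sig = debye_eval(q, freqs)
        return np.concatenate([(eps - eps_t) / eps_t, (sig - sig_t) / sig_t])

    x0 = np.array([p.eps_inf, p.delta_eps, p.tau * 1e12, max(p.sigma_s, 1e-6)])
    sol = least_squares(
        residuals,
        x0,
        bounds=([1.0, 0.0, 1e-3, 0.0], [np.inf] * 4),
        max_nfev=1000,
        xtol=1e-14,
        ftol=1e-14,
    )
    if not sol.success:
        raise FitError(
            f"Cole-Cole to Debye fit did not converge: {sol.message}; "
            f"residual trace tail {sol.fun[-5:]}"
        )
    return DispersionParams(
        "debye", float(sol.x[0]), float(sol.x[1]), float(sol.x[2]) * 1e-12,
        float(sol.x[3]),
    )


def build_bound_curves(nominal: DispersionParams, bound_fraction: float):
    """Return ``(lower, upper)`` curve evaluators scaling both properties by
    ``1 -/+ bound_fraction`` around the nominal curve."""
    if bound_fraction < 0:
        raise ParameterError("bound_fraction must be >= 0")
    if bound_fraction >= 1:
        raise ParameterError("bound_fraction must be < 1")

    def lower(f_ghz):
        eps, sig = eval_dispersion(nominal, f_ghz)
        return (1.0 - bound_fraction) * eps, (1.0 - bound_fraction) * sig

    def upper(f_ghz):
        eps, sig = eval_dispersion(nominal, f_ghz)
        return (1.0 + bound_fraction) * eps, (1.0 + bound_fraction) * sig

    return lower, upper


def map_intensity_to_property(w_intensity, i_min: float, i_max: float,
                              lower_val: float, upper_val: float):
    """Piecewise-linear map from water-channel intensity to a property value.

    Intensity ``i_min`` maps to ``lower_val``, ``i_max`` to ``upper_val``;
    ``i_min == i_max`` returns the midpoint.  Intensities outside the range
    are clamped with a warning.
    """
    w = np.asarray(w_intensity, dtype=np.float64)
    if i_max < i_min:
        raise ParameterError("i_max must be >= i_min")
    if i_max == i_min:
        return np.full_like(w, 0.5 * (lower_val + upper_val)) if w.ndim else (
            0.5 * (lower_val + upper_val)
        )
    if np.any(w < i_min) or np.any(w > i_max):
        warnings.warn("intensity outside [i_min, i_max]: clamped")
        w = np.clip(w, i_min, i_max)
    t = (w - i_min) / (i_max - i_min)
    return lower_val + t * (upper_val - lower_val)


class TissueCurveTable:
    """Dispersion curves for every label of both vocabularies.

    Loaded from a CSV with columns tissue, model, eps_inf, delta_eps, tau_ps,
    sigma_s, alpha, bound_fraction.  Background maps to free space (eps_r=1,
    sigma=0); benign tumors are mapped inside the fibroglandular envelope and
    carry no row of their own.
    """

    def __init__(self, params: dict[str, DispersionParams],
                 bound_fractions: dict[str, float]):
        self.params = params
        self.bound_fractions = bound_fractions
        self._malignant_debye: DispersionParams | None = None

    @classmethod
    def from_csv(cls, path) -> "TissueCurveTable":
        df = pd.read_csv(path, comment="#")
        params: dict[str, DispersionParams] = {}
        bounds: dict[str, float] = {}
        for row in df.itertuples(index=False):
            params[row.tissue] = DispersionParams(
                model=row.model,
                eps_inf=float(row.eps_inf),
                delta_eps=float(row.delta_eps),
                tau=float(row.tau_ps) * 1e-12,
                sigma_s=float(row.sigma_s),
                alpha=float(row.alpha),
            )
            bounds[row.tissue] = float(row.bound_fraction)
        return cls(params, bounds)

    @classmethod
    def default(cls) -> "TissueCurveTable":
        ref = resources.files("mwibreast.data").joinpath("tissue_dielectrics.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def curve(self, tissue: str) -> DispersionParams:
        try:
            return self.params[tissue]
        except KeyError:
            raise TableError(f"no dielectric curve for tissue {tissue!r}") from None

    def malignant_debye(self) -> DispersionParams:
        """Band-limited Debye equivalent of the malignant Cole-Cole curve."""
        if self._malignant_debye is None:
            p = self.curve("malignant_tumor")
            self._malignant_debye = cole_to_debye(p) if p.model == "cole_cole" else p
        return self._malignant_debye


# per-label (lower, upper) envelope tissue names in the detailed dialect;
# None means the label's own curve on that side (clamp at class extremes)
_DETAILED_ENVELOPES: dict[int, tuple[str, str]] = {
    1: ("fibroglandular_low", "fibroglandular_median"),
    2: ("fibroglandular_low", "fibroglandular_high"),
    3: ("fibroglandular_median", "fibroglandular_high"),
    4: ("fat_high", "fibroglandular_low"),  # transition between the classes
    5: ("fat_low", "fat_median"),
    6: ("fat_low", "fat_high"),
    7: ("fat_median", "fat_high"),
}


def _label_envelope(label: int, table: TissueCurveTable, f_ghz: float,
                    dialect: str) -> tuple[tuple[float, float], tuple[float, float]]:
    """(lower (eps, sigma), upper (eps, sigma)) envelope values at f."""
    if label in (-2, -1):
        tissue = "skin" if label == -2 else "muscle"
        frac = table.bound_fractions.get(tissue, 0.05)
        lower, upper = build_bound_curves(table.curve(tissue), frac)
        return lower(f_ghz), upper(f_ghz)
    if label == -4:  # benign tumors span the fibroglandular envelope
        lo = eval_dispersion(table.curve("fibroglandular_low"), f_ghz)
        hi = eval_dispersion(table.curve("fibroglandular_high"), f_ghz)
        return lo, hi
    if label == -3:
        nominal = eval_dispersion(table.malignant_debye(), f_ghz)
        return nominal, nominal
    if dialect == "simple" and label == 1:
        # fat + fibroglandular lumped: the breast is treated as fat
        lo = eval_dispersion(table.curve("fat_low"), f_ghz)
        hi = eval_dispersion(table.curve("fat_high"), f_ghz)
        return lo, hi
    if label in _DETAILED_ENVELOPES:
        lo_name, hi_name = _DETAILED_ENVELOPES[label]
        return (
            eval_dispersion(table.curve(lo_name), f_ghz),
            eval_dispersion(table.curve(hi_name), f_ghz),
        )
    raise TableError(f"no envelope defined for label {label}")


def generate_property_maps(
    labels: Volume3D,
    W: Volume3D,
    table: TissueCurveTable | None = None,
    f_ghz: float = 6.0,
    dialect: str = "detailed",
) -> PropertyMaps:
    """Build relative-permittivity and effective-conductivity maps at one
    frequency.

    Per voxel: background -> (1, 0); each tissue label maps its water-channel
    intensity linearly between that label's lower/upper envelope curves,
    using the per-exam, per-label intensity extremes; malignant tumors take
    the nominal converted-Debye curve.  Output volumes are float64 with the
    input geometry.
    """
    f_ghz = validate_frequency(f_ghz)
    check_same_geometry(labels, W)
    table = table or TissueCurveTable.default()
    vocab = DETAILED_LABELS if dialect == "detailed" else SIMPLE_LABELS

    lab = labels.data
    wdat = W.data.astype(np.float64)
    eps = np.ones(lab.shape, dtype=np.float64)
    sig = np.zeros(lab.shape, dtype=np.float64)

    for label in np.unique(lab):
        label = int(label)
        if label == 0:
            continue  # background stays free space
        if label not in vocab:
            raise TableError(
                f"label {label} is not part of the {dialect!r} vocabulary"
            )
        sel = lab == label
        (eps_lo, sig_lo), (eps_hi, sig_hi) = _label_envelope(
            label, table, f_ghz, dialect
        )
        w_sel = wdat[sel]
        i_min, i_max = float(w_sel.min()), float(w_sel.max())
        eps[sel] = map_intensity_to_property(w_sel, i_min, i_max, eps_lo, eps_hi)
        sig[sel] = map_intensity_to_property(w_sel, i_min, i_max, sig_lo, sig_hi)

    return PropertyMaps(
        permittivity=labels.with_data(eps),
        conductivity=labels.with_data(sig),
        frequency_ghz=f_ghz,
    )


__all__ = [
    "EPS0",
    "DispersionParams",
    "TissueCurveTable",
    "PropertyMaps",
    "frequency_grid",
    "validate_frequency",
    "debye_eval",
    "cole_cole_eval",
    "eval_dispersion",
    "cole_to_debye",
    "build_bound_curves",
    "map_intensity_to_property",
    "generate_property_maps",
]
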