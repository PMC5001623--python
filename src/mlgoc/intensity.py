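"""Additive image-formation model for overlapping fluorescent nuclei.

In wide-field fluorescence imaging at low numerical aperture, measured
intensity is proportional to fluorophore density, so nuclei stacked on
top of each other contribute additively: a pixel covered by n nuclei has
mean intensity mu_minus + n*delta_mu and variance
sigma2_minus + n*delta_sigma2, where (mu_minus, sigma2_minus) describe
the background ("dark noise") and (delta_mu, delta_sigma2) the per-cell
increments.  The data energy scores a multi-layer phase field through
its counting field phi_plus = sum_i (1 + phi_i)/2, which plays the role
of the (continuous) overlap count n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "ImageFormationParams",
    "predict_mean_var",
    "estimate_params_mle",
    "data_energy",
    "data_gradient",
    "EstimationError",
]


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ImageFormationParams:
    """Additive-model parameters (all in native image intensity units).

    mu_minus / sigma2_minus: background mean and variance;
    delta_mu / delta_sigma2: mean and variance increment per overlapping
    cell.  Single-cell statistics are mu_plus = mu_minus + delta_mu,
    sigma2_plus = sigma2_minus + delta_sigma2.
    """

    mu_minus: float
    sigma2_minus: float
    delta_mu: float
    delta_sigma2: float = 0.0

    def __post_init__(self):
        if self.sigma2_minus <= 0:
            raise ValueError("sigma2_minus must be > 0")
        if self.delta_mu <= 0:
            raise ValueError("delta_mu must be > 0")
        if self.delta_sigma2 < 0:
            raise ValueError("delta_sigma2 must be >= 0")

    @property
    def mu_plus(self) -> float:
        return self.mu_minus + self.delta_mu

    @property
    def sigma2_plus(self) -> float:
        return self.sigma2_minus + self.delta_sigma2


def predict_mean_var(params: ImageFormationParams, n) -> tuple:
    """Mean and variance of the intensity under n overlapping cells.

    n may be fractional (the counting field is continuous); negative n
    is clamped to 0 with a warning.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        warnings.warn("negative overlap count clamped to 0", stacklevel=2)
        n = np.maximum(n, 0.0)
    mean = params.mu_minus + n * params.delta_mu
    var = params.sigma2_minus + n * params.delta_sigma2
    if mean.ndim == 0:
        return float(mean), float(var)
    return mean, var


def _region_stats(image: np.ndarray, mask: np.ndarray, name: str) -> tuple[float, float]:
    vals = image[mask]
    if vals.size == 0:
        raise EstimationError(f"empty {name} mask")
    mu = float(np.mean(vals))
    var = float(np.var(vals))  # biased MLE variance
    if var == 0.0:
        raise EstimationError(f"zero intensity variance in {name} region")
    return mu, var


def estimate_params_mle(
    image: np.ndarray,
    bg_mask: np.ndarray | None = None,
    single_mask: np.ndarray | None = None,
) -> ImageFormationParams:
    """Gaussian maximum-likelihood estimates of the model parameters.

    With masks given, each region's mean and (biased) variance are the
    MLEs; delta_mu = mu_plus - mu_minus and delta_sigma2 is floored at 0
    (overlap cannot reduce variance under the model).  Without masks, a
    rough split is derived from a global Otsu threshold with the
    boundary eroded away by 2 px on each side to exclude mixed pixels.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if (bg_mask is None) != (single_mask is None):
        raise ValueError("provide both masks or neither")
    if bg_mask is None:
        fg = image > threshold_otsu(image)
        yy, xx = np.mgrid[-2:3, -2:3]
        selem = yy * yy + xx * xx <= 4  # 2-px disk
        single_mask = ndimage.binary_erosion(fg, selem)
        bg_mask = ~ndimage.binary_dilation(fg, selem)
        if not single_mask.any() or not bg_mask.any():
            raise EstimationError("Otsu split produced an empty region")
    else:
        bg_mask = np.asarray(bg_mask, dtype=bool)
        single_mask = np.asarray(single_mask, dtype=bool)
        if np.any(bg_mask & single_mask):
            raise ValueError("background and single-cell masks overlap")
    mu_m, var_m = _region_stats(image, bg_mask, "background")
    mu_p, var_p = _region_stats(image, single_mask, "single-cell")
    if mu_p <= mu_m:
        raise EstimationError("single-cell mean does not exceed background mean")
    return ImageFormationParams(
        mu_minus=mu_m,
        sigma2_minus=var_m,
        delta_mu=mu_p - mu_m,
        delta_sigma2=max(0.0, var_p - var_m),
    )


def _as_phi_plus(obj) -> tuple[np.ndarray, int | None]:
    """Accept a counting field, a (k,H,W) stack, or a MultiLayerPhaseField."""
    layers = getattr(obj, "layers", obj)
    arr = np.asarray(layers, dtype=float)
    if arr.ndim == 3:
        return np.sum(0.5 * (1.0 + arr), axis=0), arr.shape[0]
    return arr, None


def _residual_terms(phi_plus, image, params):
    m = params.mu_minus + phi_plus * params.delta_mu
    pos = phi_plus > 0
    v = params.sigma2_minus + np.where(pos, phi_plus, 0.0) * params.delta_sigma2
    return m, v, pos


def data_energy(
    phi_plus: np.ndarray,
    image: np.ndarray,
    params: ImageFormationParams,
    gamma_d: float,
    include_log_term: bool = True,
) -> float:
    """Gaussian negative log-likelihood data term.

    E = gamma_d * sum [ (I - mu_minus - phi_plus*delta_mu)^2 / (2 v)
                        + (1/2) ln v ]        (log term optional)

    with v = sigma2_minus + max(phi_plus, 0)*delta_sigma2.  Minimal when
    phi_plus matches the local overlap count; the variance argument is
    clamped at 0 because phase fields transiently undershoot -1.
    """
    if gamma_d <= 0:
        raise ValueError("gamma_d must be > 0")
    phi_plus, _ = _as_phi_plus(phi_plus)
    image = np.asarray(image, dtype=float)
    if phi_plus.shape != image.shape:
        raise ValueError("field and image shapes differ")
    m, v, _ = _residual_terms(phi_plus, image, params)
    e = np.sum((image - m) ** 2 / (2.0 * v))
    if include_log_term:
        e += 0.5 * np.sum(np.log(v))
    return gamma_d * float(e)


def data_gradient_wrt_phi_plus(
    phi_plus: np.ndarray,
    image: np.ndarray,
    params: ImageFormationParams,
    gamma_d: float,
    include_log_term: bool = True,
) -> np.ndarray:
    """dE_data/dphi_plus, shared by every layer (see data_gradient)."""
    if gamma_d <= 0:
        raise ValueError("gamma_d must be > 0")
    phi_plus, _ = _as_phi_plus(phi_plus)
    image = np.asarray(image, dtype=float)
    m, v, pos = _residual_terms(phi_plus, image, params)
    resid = image - m
    g = -params.delta_mu * resid / v
    if params.delta_sigma2 != 0.0:
        g -= np.where(pos, params.delta_sigma2 * resid**2 / (2.0 * v**2), 0.0)
        if include_log_term:
            g += np.where(pos, params.delta_sigma2 / (2.0 * v), 0.0)
    return gamma_d * g


def data_gradient(
    field,
    image: np.ndarray,
    params: ImageFormationParams,
    gamma_d: float,
    n_layers: int | None = None,
    include_log_term: bool = True,
) -> np.ndarray:
    """Per-layer functional derivative of the data energy.

    phi_plus depends on each layer only through the sum, with
    d phi_plus / d phi_i = 1/2, so the gradient is identical across
    layers; returned with shape (n_layers, H, W).  ``field`` may be a
    multi-layer field (n_layers inferred) or a counting field (n_layers
    required).
    """
    phi_plus, k = _as_phi_plus(field)
    if n_layers is None:
        n_layers = k
    if n_layers is None:
        raise ValueError("n_layers required when passing a counting field")
    g = 0.5 * data_gradient_wrt_phi_plus(
        phi_plus, image, params, gamma_d, include_log_term
    )
    return np.broadcast_to(g, (n_layers,) + g.shape).copy()
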