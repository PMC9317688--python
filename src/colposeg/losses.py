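"""Training objectives for unsupervised segmentation.

The central objective is the CT-loss: the sum of a cross-entropy term between
the per-pixel class-probability map (the *response map* r') and its own argmax
*pseudo segmentation mask* c, and an anisotropic total-variation term on the
response map.  Also provided: the mean-squared reconstruction error used for
full-autoencoder updates, the soft N-cut loss of the graph-cut W-Net baseline,
and the confidence score (mean per-pixel maximum probability) used for model
selection.

All functions take channel-last arrays — a response map is ``(H, W, K)`` (an
optional leading batch axis is accepted) — and return python floats.  Each
loss has an analytic gradient companion used by the training loops; gradients
are with respect to the (already normalized) response map, with the pseudo
mask treated as a constant.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

EPS = 1e-8

__all__ = [
    "AffinityParams",
    "pseudo_mask",
    "cross_entropy_loss",
    "cross_entropy_grad",
    "total_variation_loss",
    "total_variation_grad",
    "ct_loss",
    "reconstruction_loss",
    "reconstruction_grad",
    "confidence_score",
    "soft_ncut_loss",
    "soft_ncut_grad",
]

_ce_clamp_warned = False


@dataclass
class AffinityParams:
    """Gaussian pixel-affinity parameters for the soft N-cut loss.

    ``sigma_intensity`` is on a 0-255 colour scale; ``sigma_spatial`` in
    pixels of the (pooled) grid; pairs farther apart than ``radius``
    (Euclidean) have zero affinity.  ``pool_factor`` average-pools image and
    response before the graph is built, trading resolution for memory.
    """

    sigma_intensity: float = 10.0
    sigma_spatial: float = 4.0
    radius: int = 5
    pool_factor: int = 2

    def __post_init__(self):
        if self.sigma_intensity <= 0 or self.sigma_spatial <= 0:
            raise ValueError("sigma parameters must be positive")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        f = self.pool_factor
        if f < 1 or (f & (f - 1)):
            raise ValueError("pool_factor must be a power of 2")


def _as_batch(arr: np.ndarray, ndim_single: int) -> np.ndarray:
    if arr.ndim == ndim_single:
        return arr[None]
    if arr.ndim == ndim_single + 1:
        return arr
    raise ValueError(f"expected {ndim_single}- or {ndim_single + 1}-d array, got {arr.ndim}-d")


def pseudo_mask(response: np.ndarray) -> np.ndarray:
    """Per-pixel argmax labels of a response map; ties go to the lowest class."""
    return np.argmax(response, axis=-1)


def cross_entropy_loss(response: np.ndarray, pseudo: np.ndarray,
                       reduction: str = "mean") -> float:
    """Cross entropy of the response map against a (detached) label map.

    ``reduction='mean'`` averages -log r'[c] over pixels (default, so the loss
    scale is independent of image size); ``'sum'`` is the plain per-pixel sum.
    Probabilities are clamped at 1e-8 before the log.
    """
    global _ce_clamp_warned
    r = _as_batch(response, 3)
    c = _as_batch(np.asarray(pseudo), 2)
    if r.shape[:3] != c.shape:
        raise ValueError(f"shape mismatch: response {r.shape[:3]} vs pseudo {c.shape}")
    picked = np.take_along_axis(r, c[..., None], axis=-1)[..., 0]
    if np.any(picked < EPS) and not _ce_clamp_warned:
        logger.warning("cross-entropy: probabilities below %.0e clamped", EPS)
        _ce_clamp_warned = True
    nll = -np.log(np.maximum(picked, EPS))
    if reduction == "mean":
        return float(nll.mean())
    if reduction == "sum":
        return float(nll.sum())
    raise ValueError(f"unknown reduction {reduction!r}")


def cross_entropy_grad(response: np.ndarray, pseudo: np.ndarray,
                       reduction: str = "mean") -> np.ndarray:
    """d(cross_entropy_loss)/d(response); zero where the pixel label differs."""
    r = _as_batch(response, 3)
    c = _as_batch(np.asarray(pseudo), 2)
    picked = np.maximum(np.take_along_axis(r, c[..., None], axis=-1)[..., 0], EPS)
    grad = np.zeros_like(r)
    np.put_along_axis(grad, c[..., None], (-1.0 / picked)[..., None], axis=-1)
    if reduction == "mean":
        grad /= picked.size
    return grad.reshape(response.shape)


def _tv_diffs(r: np.ndarray, strict_bounds: bool):
    """Horizontal and vertical neighbour differences of a (N,H,W,K) map."""
    dh = r[:, :, 1:, :] - r[:, :, :-1, :]
    dv = r[:, 1:, :, :] - r[:, :-1, :, :]
    if strict_bounds:
        dh = dh[:, :-1, :, :]
        dv = dv[:, :, :-1, :]
    return dh, dv


def total_variation_loss(response: np.ndarray, reduction: str = "sum",
                         strict_bounds: bool = False) -> float:
    """Anisotropic total variation: L1 differences over neighbouring pixels.

    By default every valid horizontal and vertical neighbour pair contributes
    (``reduction='sum'``); ``'mean'`` divides by the number of scalar
    difference terms so the value is resolution-independent.
    ``strict_bounds`` jointly truncates both indices (dropping last-row
    horizontal and last-column vertical pairs), the literal reading of the
    printed summation bounds.
    """
    r = _as_batch(response, 3)
    if r.shape[1] < 2 or r.shape[2] < 2:
        raise ValueError("total variation needs H, W >= 2")
    dh, dv = _tv_diffs(r, strict_bounds)
    total = np.abs(dh).sum() + np.abs(dv).sum()
    if reduction == "sum":
        return float(total)
    if reduction == "mean":
        return float(total / (dh.size + dv.size))
    raise ValueError(f"unknown reduction {reduction!r}")


def total_variation_grad(response: np.ndarray, reduction: str = "sum",
                         strict_bounds: bool = False) -> np.ndarray:
    r = _as_batch(response, 3)
    dh, dv = _tv_diffs(r, strict_bounds)
    sh, sv = np.sign(dh), np.sign(dv)
    grad = np.zeros_like(r)
    hh = sh.shape[1]  # rows kept for horizontal pairs (H or H-1 when strict)
    wv = sv.shape[2]
    grad[:, :hh, 1:, :] += sh
    grad[:, :hh, :-1, :] -= sh
    grad[:, 1:, :wv, :] += sv
    grad[:, :-1, :wv, :] -= sv
    if reduction == "mean":
        grad /= (dh.size + dv.size)
    return grad.reshape(response.shape)


def ct_loss(response: np.ndarray, pseudo: np.ndarray, tv_weight: float = 1.0,
            ce_reduction: str = "mean", tv_reduction: str = "sum",
            strict_bounds: bool = False) -> float:
    """Cross-entropy + ``tv_weight`` x total-variation (the CT-loss)."""
    if tv_weight < 0:
        raise ValueError("tv_weight must be >= 0")
    ce = cross_entropy_loss(response, pseudo, reduction=ce_reduction)
    if tv_weight == 0:
        return ce
    return ce + tv_weight * total_variation_loss(response, reduction=tv_reduction,
                                                 strict_bounds=strict_bounds)


def ct_loss_grad(response: np.ndarray, pseudo: np.ndarray, tv_weight: float = 1.0,
                 ce_reduction: str = "mean", tv_reduction: str = "sum",
                 strict_bounds: bool = False) -> np.ndarray:
    grad = cross_entropy_grad(response, pseudo, reduction=ce_reduction)
    if tv_weight:
        grad = grad + tv_weight * total_variation_grad(response, reduction=tv_reduction,
                                                       strict_bounds=strict_bounds)
    return grad


def reconstruction_loss(image: np.ndarray, reconstruction: np.ndarray) -> float:
    """Mean squared error over all scalar elements (pixels x channels)."""
    x = np.asarray(image, dtype=np.float64)
    y = np.asarray(reconstruction, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2))


def reconstruction_grad(image: np.ndarray, reconstruction: np.ndarray) -> np.ndarray:
    """d(MSE)/d(reconstruction)."""
    if image.shape != reconstruction.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {reconstruction.shape}")
    return (2.0 / image.size) * (reconstruction - image)


def confidence_score(response: np.ndarray) -> float:
    """Mean over pixels of the maximum class probability; in [1/K, 1].

    Uses a correctly rounded sum so a uniform map scores exactly 1/K.
    """
    r = _as_batch(response, 3)
    mx = r.max(axis=-1)
    return math.fsum(mx.ravel().tolist()) / mx.size


# ---------------------------------------------------------------------------
# soft N-cut loss (graph-cut W-Net baseline)
# ---------------------------------------------------------------------------

def _avg_pool(a: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return a
    h, w, c = a.shape
    if h % f or w % f:
        raise ValueError(f"pool_factor {f} must divide image dims {h}x{w}")
    return a.reshape(h // f, f, w // f, f, c).mean(axis=(1, 3))


def _disc_offsets(radius: int):
    offs = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if di * di + dj * dj <= radius * radius:
                offs.append((di, dj))
    return offs


def _ncut_terms(image: np.ndarray, response: np.ndarray, params: AffinityParams):
    """Pooled maps, per-class (numerator, denominator) and W @ p_k, degree."""
    img = _avg_pool(np.asarray(image, dtype=np.float64), params.pool_factor) * 255.0
    resp = _avg_pool(np.asarray(response, dtype=np.float64), params.pool_factor)
    hp, wp, k = resp.shape
    if params.radius > min(hp, wp):
        raise ValueError("affinity radius exceeds pooled image size")
    si2 = params.sigma_intensity ** 2
    sx2 = params.sigma_spatial ** 2
    deg = np.zeros((hp, wp))
    wp_k = np.zeros((hp, wp, k))
    for di, dj in _disc_offsets(params.radius):
        # valid alignment of u and u + (di, dj)
        r0, r1 = max(0, -di), min(hp, hp - di)
        c0, c1 = max(0, -dj), min(wp, wp - dj)
        a = img[r0:r1, c0:c1]
        b = img[r0 + di:r1 + di, c0 + dj:c1 + dj]
        w = np.exp(-((a - b) ** 2).sum(-1) / si2) * np.exp(-(di * di + dj * dj) / sx2)
        deg[r0:r1, c0:c1] += w
        wp_k[r0:r1, c0:c1] += w[..., None] * resp[r0 + di:r1 + di, c0 + dj:c1 + dj]
    num = (resp * wp_k).sum(axis=(0, 1))
    den = (resp * deg[..., None]).sum(axis=(0, 1))
    return resp, deg, wp_k, num, den


def soft_ncut_loss(image: np.ndarray, response: np.ndarray,
                   params: AffinityParams | None = None) -> float:
    """Soft normalized-cut loss: K minus the sum of normalized associations.

    Affinities are Gaussian in colour (0-255 scale) and in space, truncated at
    ``params.radius``; image and response are average-pooled by
    ``params.pool_factor`` first.  The value lies in [0, K].
    """
    params = params or AffinityParams()
    _, _, _, num, den = _ncut_terms(image, response, params)
    k = num.size
    total = 0.0
    for kk in range(k):
        if den[kk] <= 1e-12:
            warnings.warn(f"soft N-cut: class {kk} has zero soft assignment", stacklevel=2)
            continue
        total += num[kk] / den[kk]
    return float(k - total)


def soft_ncut_grad(image: np.ndarray, response: np.ndarray,
                   params: AffinityParams | None = None) -> np.ndarray:
    """Gradient of the soft N-cut loss w.r.t. the (un-pooled) response map."""
    params = params or AffinityParams()
    resp, deg, wp_k, num, den = _ncut_terms(image, response, params)
    grad_pooled = np.zeros_like(resp)
    for kk in range(resp.shape[-1]):
        if den[kk] <= 1e-12:
            continue
        # d(assoc_k)/dp_k = (2 W p_k) / d_k - n_k * deg / d_k^2 ; loss has -assoc
        grad_pooled[..., kk] = -(2.0 * wp_k[..., kk] / den[kk]
                                 - num[kk] * deg / den[kk] ** 2)
    f = params.pool_factor
    if f > 1:
        # average pooling spreads the gradient uniformly over each f x f block
        grad_pooled = grad_pooled / (f * f)
        grad = np.repeat(np.repeat(grad_pooled, f, axis=0), f, axis=1)
    else:
        grad = grad_pooled
    return grad.astype(response.dtype) if hasattr(response, "dtype") else grad
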