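"""Perturbation-structure and image-statistics metrics.

``edge_strength`` renders a perturbation about mid-gray, bilateral
filters it (edge-preserving smoothing), runs a Canny detector, and
counts the active unit edge elements in the resulting binary map. The
count depends on the filter parameters, so every reported value should
travel with its :class:`EdgeParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.metrics import structural_similarity
from skimage.restoration import denoise_bilateral

__all__ = [
    "EdgeParams",
    "edge_strength",
    "ms_ssim",
    "luminance_contrast",
    "MS_SSIM_WEIGHTS",
]

#: Per-scale weights of the standard 5-scale multi-scale SSIM.
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class EdgeParams:
    """Bilateral-filter and Canny parameters on the 0-255 intensity scale."""

    bilateral_sigma_spatial: float = 3.0
    bilateral_sigma_range: float = 10.0  # intensity levels
    canny_sigma: float = 1.4
    # thresholds are calibrated to perturbation-scale inputs (a delta of
    # a few intensity levels about mid-gray), not full-contrast images
    canny_low: float = 5.0  # intensity levels
    canny_high: float = 12.0

    def __post_init__(self) -> None:
        if not self.canny_low < self.canny_high:
            raise ValueError("Canny low threshold must be below the high threshold")
        if min(self.bilateral_sigma_spatial, self.bilateral_sigma_range, self.canny_sigma) <= 0:
            raise ValueError("filter sigmas must be positive")


def edge_strength(delta: np.ndarray, params: EdgeParams = EdgeParams()) -> int:
    """Count of unit edge elements in a bilateral-filtered perturbation.

    The perturbation is rendered as luminance about mid-gray
    (128 + delta, clipped to [0, 255]) so that both filters operate on a
    displayable single-channel image.
    """
    d = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("perturbation contains non-finite values")
    if d.ndim == 3:
        d = d @ _LUMA
    rendered = np.clip(128.0 + d, 0.0, 255.0) / 255.0
    if np.ptp(rendered) == 0:
        return 0  # constant field: no edges by definition
    smoothed = denoise_bilateral(
        rendered,
        sigma_spatial=params.bilateral_sigma_spatial,
        sigma_color=params.bilateral_sigma_range / 255.0,
    )
    edges = canny(
        smoothed,
        sigma=params.canny_sigma,
        low_threshold=params.canny_low / 255.0,
        high_threshold=params.canny_high / 255.0,
    )
    return int(edges.sum())


def _downsample(img: np.ndarray) -> np.ndarray:
    """2x2 mean-pool (pad-free dyadic pyramid step)."""
    h, w = img.shape[:2]
    img = img[: h - h % 2, : w - w % 2]
    return 0.25 * (img[::2, ::2] + img[1::2, ::2] + img[::2, 1::2] + img[1::2, 1::2])


def ms_ssim(
    a: np.ndarray,
    b: np.ndarray,
    weights: tuple[float, ...] = MS_SSIM_WEIGHTS,
    win_size: int = 7,
) -> float:
    """Multi-scale structural similarity on [0, 255] images.

    Implemented as the weighted geometric mean of mean SSIM over a
    dyadic pyramid with the standard 5-scale weights (weights are
    renormalized to sum to one). Symmetric in its arguments; 1.0 iff the
    images are identical. Raises if the coarsest scale falls below the
    SSIM window.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("images must share a shape")
    if x.ndim == 3:
        x = x @ _LUMA
        y = y @ _LUMA
    n_scales = len(weights)
    min_side = min(x.shape) // 2 ** (n_scales - 1)
    if min_side < win_size:
        raise ValueError(
            f"image too small for {n_scales} scales with win_size {win_size}; "
            f"coarsest side would be {min_side}"
        )
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    log_total = 0.0
    for level, wl in enumerate(w):
        s = structural_similarity(x, y, win_size=win_size, data_range=255.0)
        s = max(float(s), 1e-12)  # geometric mean needs positivity
        log_total += wl * np.log(s)
        if level < n_scales - 1:
            x = _downsample(x)
            y = _downsample(y)
    return float(np.exp(log_total))


def luminance_contrast(image: np.ndarray) -> tuple[float, float]:
    """(mean intensity, RMS contrast) over all pixels and channels."""
    x = np.asarray(image, dtype=float)
    return float(x.mean()), float(x.std())
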