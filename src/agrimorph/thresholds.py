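"""Global-threshold segmentation baselines: Otsu and RATS.

Both methods pick a single grey level for the whole image — Otsu by
maximizing the between-class variance of the histogram split, RATS (Robust
Automatic Threshold Selection) as the gradient-weighted mean intensity

    T = sum(w f) / sum(w),   w = |grad f|  where |grad f| > eta * lambda

with the Sobel operator and sensitivity lambda.  They serve as the reference
points against which the local, max-tree-based segmentation is compared:
global decisions degrade under uneven lighting, textured soil and low
vegetation content (RATS may then be undefined altogether).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BinaryMask, NDVIImage

__all__ = ["RATSParams", "otsu_threshold", "rats_threshold",
           "sobel_magnitude", "apply_threshold"]


@dataclass
class RATSParams:
    """RATS parameters: Sobel sensitivity ``lam`` (= 3 by convention) and
    background-noise control ``eta`` (non-negative; dataset-dependent, no
    universal default exists — tune per acquisition setup)."""

    lam: float = 3.0
    eta: float = 1.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


def _grey(image) -> np.ndarray:
    arr = image.values if isinstance(image, NDVIImage) else np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    return arr


def otsu_threshold(image) -> int:
    """Grey level maximizing the between-class variance of the split.

    Pixels <= t form the background class, pixels > t the foreground; the
    returned t maximizes omega0 * omega1 * (mu0 - mu1)^2, with ties resolved
    to the lowest threshold.  A constant image has no valid split.
    """
    arr = _grey(image)
    hist = np.bincount(arr.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    total = hist.sum()
    omega0 = np.cumsum(hist) / total              # weight of class <= t
    cum_mean = np.cumsum(hist * np.arange(256)) / total
    mean_total = cum_mean[-1]
    omega1 = 1.0 - omega0
    with np.errstate(invalid="ignore", divide="ignore"):
        variance = (mean_total * omega0 - cum_mean) ** 2 / (omega0 * omega1)
    variance[~np.isfinite(variance)] = -np.inf
    return int(np.argmax(variance[:255]))


def sobel_magnitude(image) -> np.ndarray:
    """Sobel gradient magnitude sqrt(gx^2 + gy^2), replicate borders."""
    arr = _grey(image).astype(np.float64)
    gx = ndimage.sobel(arr, axis=1, mode="nearest")
    gy = ndimage.sobel(arr, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def rats_threshold(image, params: RATSParams | None = None) -> float:
    """Gradient-weighted mean intensity threshold (may be fractional).

    Raises when no pixel's gradient exceeds the noise level eta*lam — a
    uniform or low-content image leaves the threshold not well-defined.
    """
    params = params or RATSParams()
    arr = _grey(image).astype(np.float64)
    grad = sobel_magnitude(arr)
    w = np.where(grad > params.eta * params.lam, grad, 0.0)
    total = w.sum()
    if total == 0:
        raise ValueError("RATS threshold not well-defined: all weights zero")
    return float((w * arr).sum() / total)


def apply_threshold(image, t: float) -> BinaryMask:
    """Foreground mask where the image value strictly exceeds ``t``."""
    return BinaryMask(values=_grey(image) > t)
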