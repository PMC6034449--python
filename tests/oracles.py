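"""Brute-force reference implementations used as independent oracles.

Everything here works directly from first principles (explicit threshold
decomposition, exhaustive scans, shapely geometry) and shares no code with
the package's incremental/tree-based routes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union


def _structure(connectivity: int) -> np.ndarray:
    return (np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
            if connectivity == 4 else np.ones((3, 3), dtype=int))


def upper_level_components(img: np.ndarray, connectivity: int = 4
                           ) -> set[tuple[int, frozenset]]:
    """All distinct peak components, each at its highest level.

    Enumerates the connected components of every upper level set
    L_k = {f >= k}; components identical across consecutive levels are kept
    once at the highest k (canonical max-tree node set).
    """
    img = np.asarray(img)
    structure = _structure(connectivity)
    best: dict[frozenset, int] = {}
    for k in range(int(img.min()), int(img.max()) + 1):
        labels, n = ndimage.label(img >= k, structure=structure)
        for i in range(1, n + 1):
            pixels = frozenset(zip(*np.nonzero(labels == i)))
            if pixels not in best or best[pixels] < k:
                best[pixels] = k
    return {(k, pixels) for pixels, k in best.items()}


def stacked_area_opening(img: np.ndarray, t_area: int, connectivity: int = 4
                         ) -> np.ndarray:
    """Area opening by stacking binary area openings of every level set."""
    img = np.asarray(img)
    structure = _structure(connectivity)
    out = np.full(img.shape, int(img.min()), dtype=np.int64)
    for k in range(int(img.min()) + 1, int(img.max()) + 1):
        labels, n = ndimage.label(img >= k, structure=structure)
        if n == 0:
            continue
        areas = np.bincount(labels.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = areas[1:] >= t_area
        out[keep[labels]] = k
    return out


def regional_maxima(img: np.ndarray, connectivity: int = 4):
    """Plateaus strictly above all their neighbours: (value, rep, pixels).

    ``rep`` is the lexicographically smallest raveled pixel index of the
    plateau (the deterministic tie-break identity used throughout).
    """
    img = np.asarray(img)
    structure = _structure(connectivity)
    maxima = []
    for value in np.unique(img):
        labels, n = ndimage.label(img == value, structure=structure)
        for i in range(1, n + 1):
            plateau = labels == i
            dilated = ndimage.binary_dilation(plateau, structure=structure)
            ring = dilated & ~plateau
            if not ring.any() or img[ring].max() < value:
                flat = np.flatnonzero(plateau.ravel())
                maxima.append((int(value), int(flat.min()), plateau))
    return maxima


def brute_extinction(img: np.ndarray, connectivity: int = 4) -> dict[int, int]:
    """Grey-range extinction of every regional maximum, by exhaustive scan.

    For each maximum, thresholds are lowered one level at a time; the
    extinction is the contrast consumed when the maximum's component first
    contains a better maximum (higher value; ties broken toward the smaller
    representative pixel).  The overall best maximum never extinguishes and
    receives the full image range.
    """
    img = np.asarray(img)
    structure = _structure(connectivity)
    maxima = regional_maxima(img, connectivity)
    out: dict[int, int] = {}
    for value, rep, plateau in maxima:
        rep_yx = np.unravel_index(rep, img.shape)
        ext = int(value - img.min())  # survives everything by default
        for k in range(value, int(img.min()) - 1, -1):
            labels, _ = ndimage.label(img >= k, structure=structure)
            comp = labels == labels[rep_yx]
            beaten = any(
                (v2 > value or (v2 == value and r2 < rep))
                for v2, r2, p2 in maxima
                if r2 != rep and comp[np.unravel_index(r2, img.shape)]
            )
            if beaten:
                ext = value - k
                break
        out[rep] = ext
    return out


def component_area_at(img: np.ndarray, pixel: tuple[int, int], k: int,
                      connectivity: int = 4) -> int:
    """Area of the component of {f >= k} containing ``pixel``."""
    labels, _ = ndimage.label(np.asarray(img) >= k, structure=_structure(connectivity))
    lab = labels[pixel]
    assert lab != 0, "pixel is below the threshold"
    return int((labels == lab).sum())


def hull_area_shapely(rows, cols) -> float:
    """Convex-hull area of a pixel set, pixels taken as unit squares."""
    squares = [box(c - 0.5, r - 0.5, c + 0.5, r + 0.5)
               for r, c in zip(np.asarray(rows), np.asarray(cols))]
    return float(unary_union(squares).convex_hull.area)


def brute_otsu(img: np.ndarray) -> int:
    """Exhaustive between-class variance maximization over all thresholds."""
    values = np.asarray(img).ravel().astype(np.float64)
    best_t, best_v = None, -np.inf
    for t in range(255):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = hi.size / values.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


def brute_rats(img: np.ndarray, lam: float = 3.0, eta: float = 1.0) -> float:
    """Direct evaluation of the gradient-weighted mean threshold.

    Explicit Sobel stencils on a replicate-padded image; weights below the
    noise level eta*lam are zeroed.
    """
    arr = np.asarray(img, dtype=np.float64)
    padded = np.pad(arr, 1, mode="edge")
    h, w = arr.shape
    gx = np.zeros_like(arr)
    gy = np.zeros_like(arr)
    for dy in range(3):
        for dx in range(3):
            block = padded[dy:dy + h, dx:dx + w]
            gx += _SOBEL_X[dy, dx] * block
            gy += _SOBEL_Y[dy, dx] * block
    mag = np.sqrt(gx**2 + gy**2)
    weights = np.where(mag > eta * lam, mag, 0.0)
    total = weights.sum()
    if total == 0:
        raise ValueError("all weights zero")
    return float((weights * arr).sum() / total)


def brute_interpolated(points):
    """Interpolated precision by explicit max over recall suffixes."""
    recalls = sorted({r for r, _ in points})
    return [(r, max(p for rr, p in points if rr >= r)) for r in recalls]
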