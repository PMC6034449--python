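"""Image and mask I/O plus NDVI computation and quantization.

The pipeline consumes either 4-channel RGBN reflectance imagery, from which
the normalized difference vegetation index NDVI = (NIR - VIS)/(NIR + VIS) is
computed, or precomputed single-channel NDVI images.  All downstream
processing (max-tree construction, extinction values, growth factors) operates
on 8-bit grey levels, so real-valued NDVI in [-1, 1] is linearly quantized to
[0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
import tifffile


@dataclass(frozen=True)
class RGBNImage:
    """4-channel image: visible red, green, blue plus near infra-red.

    All channels are 2-D arrays of identical shape with finite,
    non-negative values (reflectance or raw digital counts).
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    nir: np.ndarray

    def __post_init__(self):
        shapes = {c.shape for c in (self.red, self.green, self.blue, self.nir)}
        if len(shapes) != 1 or self.red.ndim != 2:
            raise ValueError("RGBN channels must be 2-D arrays of identical shape")
        for name in ("red", "green", "blue", "nir"):
            ch = getattr(self, name)
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"channel {name!r} must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass(frozen=True)
class NDVIImage:
    """Quantized NDVI image: integer grey levels in [0, 255].

    ``computed`` records provenance: True when derived from an RGBN image,
    False when loaded directly from a single-channel file.
    """

    values: np.ndarray
    computed: bool = True

    def __post_init__(self):
        v = self.values
        if v.ndim != 2:
            raise ValueError("NDVI image must be 2-D")
        if v.size == 0:
            raise ValueError("NDVI image must be non-empty")
        if not np.issubdtype(v.dtype, np.integer):
            raise ValueError("NDVI image must be integer-valued")
        if v.min() < 0 or v.max() > 255:
            raise ValueError("NDVI grey levels must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryMask:
    """Per-pixel boolean mask; foreground (True) marks vegetation."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.dtype != bool:
            raise ValueError("mask must be a 2-D boolean array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def compute_ndvi(nir: np.ndarray, vis: np.ndarray) -> np.ndarray:
    """Per-pixel (NIR - VIS)/(NIR + VIS); zero where NIR + VIS = 0.

    Pixels with no signal in either channel carry no vegetation evidence and
    are mapped to 0 (background-like) rather than NaN.
    """
    nir = np.asarray(nir, dtype=np.float64)
    vis = np.asarray(vis, dtype=np.float64)
    if nir.shape != vis.shape:
        raise ValueError(f"channel shapes differ: {nir.shape} vs {vis.shape}")
    if np.any(nir < 0) or np.any(vis < 0):
        raise ValueError("channel values must be non-negative")
    total = nir + vis
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (nir - vis) / np.where(total > 0, total, 1.0), 0.0)
    return out


def quantize_ndvi(field: np.ndarray) -> NDVIImage:
    """Linearly map a real-valued field in [-1, 1] to 8-bit grey levels.

    v -> round((v + 1)/2 * 255) with round-half-up, so -1 -> 0, 0 -> 128,
    +1 -> 255.
    """
    field = np.asarray(field, dtype=np.float64)
    if field.size and (field.min() < -1.0 or field.max() > 1.0):
        raise ValueError("NDVI field values must lie in [-1, 1]")
    scaled = (field + 1.0) / 2.0 * 255.0
    quant = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    return NDVIImage(values=quant, computed=True)


def ndvi_from_rgbn(image: RGBNImage) -> NDVIImage:
    """Convenience: compute and quantize NDVI from an RGBN image (VIS = red)."""
    return quantize_ndvi(compute_ndvi(image.nir, image.red))


def _load_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(str(path)))
    with Image.open(path) as im:
        return np.array(im)  # np.asarray would yield a read-only view


def read_image(path) -> RGBNImage | NDVIImage:
    """Read an image file as RGBN (4 channels) or quantized NDVI (1 channel).

    Single-channel files are treated as already-quantized NDVI; 16-bit
    single-channel data are reduced to 8 bits by dropping the low byte.
    Any other channel count is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = _load_array(path)
    if arr.ndim == 2:
        if arr.dtype == np.uint16:
            arr = (arr >> 8).astype(np.uint8)
        return NDVIImage(values=arr.astype(np.uint8, copy=False), computed=False)
    if arr.ndim == 3 and arr.shape[2] == 4:
        r, g, b, n = (arr[..., i].astype(np.float64) for i in range(4))
        return RGBNImage(red=r, green=g, blue=b, nir=n)
    raise ValueError(
        f"expected 1 or 4 channels, got shape {arr.shape} in {path.name}"
    )


def write_image(image: NDVIImage | np.ndarray, path) -> None:
    """Write a single-channel 8- or 16-bit image losslessly (PNG or TIFF)."""
    path = Path(path)
    arr = image.values if isinstance(image, NDVIImage) else np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    else:
        Image.fromarray(arr).save(path)


def write_mask(mask: BinaryMask | np.ndarray, path) -> None:
    """Store a binary mask as an 8-bit PNG, 0 = background / 255 = foreground."""
    arr = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask)
    if arr.dtype != bool:
        raise ValueError("mask must be boolean")
    Image.fromarray((arr.astype(np.uint8)) * 255, mode="L").save(Path(path))


def read_mask(path) -> BinaryMask:
    """Read a 0/255-coded single-channel PNG mask back into booleans."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = _load_array(path)
    if arr.ndim != 2:
        raise ValueError(f"mask must be single-channel, got shape {arr.shape}")
    return BinaryMask(values=arr > 0)
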