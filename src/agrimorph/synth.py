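"""Seeded generator of NDVI-like field imagery with ground truth.

The generator emulates the statistical structure the segmentation pipeline
assumes: bright, locally contrasted plant regions on a darker, textured,
noisy soil background.

* soil: base grey level plus smoothed uniform noise (peak-to-peak amplitude
  kept below the marker extinction threshold, so soil maxima are exactly the
  kind of low-contrast structure the extinction filter is meant to discard),
  plus an optional linear illumination gradient;
* speckle: sparse isolated bright pixels of small prominence — spurious
  regional maxima standing in for sensor noise and registration artefacts;
* plants: two shape families rendered with coverage-based (anti-aliased)
  edges so borders ramp over 1-2 px — compact rosettes (overlapping ellipse
  lobes, the crop class) and thin elongated rotated ellipses (the weed
  class).  A plant's top is flat at its local soil level plus its contrast,
  so each plant interior contains a regional maximum.

Ground truth is the union of the >= 50%-coverage pixels; connected regions
touched by both a crop and a weed plant are labelled *mixed*.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import FEATURE_NAMES, features_from_pixels
from .io import BinaryMask, NDVIImage

__all__ = [
    "FieldSpec", "FieldSample",
    "generate_field", "generate_lowveg", "generate_toy_binary",
    "generate_region_dataset",
]

CROP = "crop"
WEED = "weed"
MIXED = "mixed"


@dataclass(frozen=True)
class FieldSpec:
    """Generation parameters; the defaults define the synthetic study
    conditions used throughout the test suite.

    Grey-level choices are tied to the pipeline defaults: soil texture
    peak-to-peak (9) and speckle prominence (2-8) sit below the marker
    extinction threshold of 10, while plant contrast (40-90) sits well above
    it — the regime the method is designed for.
    """

    height: int = 512
    width: int = 512
    soil_level: float = 70.0
    texture_amplitude: float = 9.0     # peak-to-peak, grey levels
    texture_scale: float = 6.0         # gaussian smoothing sigma, px
    gradient_amplitude: float = 8.0    # linear illumination drift, grey levels
    speckle_rate: float = 0.002        # fraction of soil pixels hit
    speckle_amplitude: tuple[float, float] = (2.0, 8.0)
    n_plants: int = 10
    crop_fraction: float = 0.6
    contrast: tuple[float, float] = (40.0, 90.0)   # over local soil
    area: tuple[float, float] = (300.0, 1500.0)    # target core area, px
    overlap_probability: float = 0.0   # weed placed overlapping a crop
    placement_margin: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.soil_level + self.contrast[1] > 255:
            raise ValueError("plant contrast + soil level must stay <= 255")
        if self.area[0] < 1:
            raise ValueError("plant areas must be >= 1 px")
        if self.n_plants < 0:
            raise ValueError("plant count must be >= 0")


@dataclass
class FieldSample:
    """A generated field: NDVI image, truth mask, region labels and table."""

    ndvi: NDVIImage
    truth: BinaryMask
    label_map: np.ndarray
    region_table: pd.DataFrame      # region_id, class, area
    plant_table: pd.DataFrame       # plant-level ground truth
    spec: FieldSpec

    def feature_table(self, image_id=0) -> pd.DataFrame:
        """Per-region 5-feature descriptors with class labels.

        Features are computed from each labelled region's explicit pixel set
        on the NDVI image — the reference route, independent of any
        segmentation — for classifier experiments on clean ground truth.
        """
        records = []
        for _, row in self.region_table.iterrows():
            rid = int(row["region_id"])
            rows_px, cols_px = np.nonzero(self.label_map == rid)
            feats = features_from_pixels(
                rows_px, cols_px, self.ndvi.values[rows_px, cols_px]
            )
            rec = {"image_id": image_id, "region_id": rid}
            rec.update(zip(FEATURE_NAMES, feats.as_array()))
            rec["label"] = row["class"]
            records.append(rec)
        return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# plant shape rasterization

_SUPERSAMPLE = 3


def _ellipse_union_coverage(ellipses, rng_extent) -> tuple[np.ndarray, int]:
    """Coverage raster of a union of ellipses given in local coordinates.

    Each ellipse is (cx, cy, a, b, theta).  Returns (coverage, half) where
    coverage is a (2*half+1)^2 float array in [0, 1] from 3x3 subsampling.
    """
    half = int(np.ceil(rng_extent)) + 1
    n = 2 * half + 1
    s = _SUPERSAMPLE
    # Subpixel sample coordinates relative to the local origin.
    offsets = (np.arange(s) + 0.5) / s - 0.5
    base = np.arange(n) - half
    xs = (base[:, None] + offsets[None, :]).ravel()
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    inside = np.zeros_like(X, dtype=bool)
    for cx, cy, a, b, theta in ellipses:
        ct, st = np.cos(theta), np.sin(theta)
        u = (X - cx) * ct + (Y - cy) * st
        v = -(X - cx) * st + (Y - cy) * ct
        inside |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    inside = inside.reshape(n, s, n, s).mean(axis=(1, 3))
    return inside.T, half  # transpose: rows = y, cols = x


def _rosette_ellipses(radius: float, n_lobes: int, rng) -> list[tuple]:
    """Compact rosette: central disk with overlapping elliptical lobes."""
    ellipses = [(0.0, 0.0, radius, radius, 0.0)]
    phase = rng.uniform(0, 2 * np.pi)
    for j in range(n_lobes):
        ang = phase + 2 * np.pi * j / n_lobes + rng.normal(0, 0.15)
        d = 0.85 * radius
        ellipses.append(
            (d * np.cos(ang), d * np.sin(ang),
             1.0 * radius, 0.55 * radius, ang)
        )
    return ellipses


def _weed_ellipses(target_area: float, rng) -> list[tuple]:
    """Thin elongated blade: one high-aspect rotated ellipse."""
    aspect = rng.uniform(8.0, 14.0)
    b = np.sqrt(target_area / (np.pi * aspect))
    a = aspect * b
    theta = rng.uniform(0, np.pi)
    return [(0.0, 0.0, a, b, theta)]


def _render_plant(cls: str, target_area: float, rng
                  ) -> tuple[np.ndarray, int]:
    """Coverage raster for one plant, rescaled once to hit the target area."""
    def build(scale=1.0):
        if cls == CROP:
            radius = scale * np.sqrt(target_area / np.pi) * 0.72
            ells = _rosette_ellipses(radius, n_lobes=rng_state["lobes"], rng=rng_shape)
            extent = 2.0 * radius
        else:
            ells = _weed_ellipses(target_area * scale**2, rng_shape)
            extent = max(e[2] for e in ells) + 1
        return _ellipse_union_coverage(ells, extent)

    # Freeze the per-plant randomness so the rescaling pass reuses it.
    rng_state = {"lobes": int(rng.integers(5, 9))}
    shape_seed = int(rng.integers(0, 2**31))
    rng_shape = np.random.default_rng(shape_seed)
    cov, half = build()
    actual = float((cov >= 0.5).sum())
    if actual > 0 and abs(actual - target_area) / target_area > 0.1:
        rng_shape = np.random.default_rng(shape_seed)
        cov, half = build(scale=np.sqrt(target_area / actual))
    return cov, half


# ---------------------------------------------------------------------------
# field assembly

def _soil(spec: FieldSpec, rng) -> np.ndarray:
    noise = rng.uniform(-1.0, 1.0, size=(spec.height, spec.width))
    smooth = ndimage.gaussian_filter(noise, spec.texture_scale, mode="reflect")
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth *= (spec.texture_amplitude / 2.0) / peak
    soil = spec.soil_level + smooth
    if spec.gradient_amplitude > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:spec.height, 0:spec.width]
        ramp = (np.cos(theta) * xx / max(spec.width - 1, 1)
                + np.sin(theta) * yy / max(spec.height - 1, 1))
        ramp -= ramp.min()
        if ramp.max() > 0:
            ramp /= ramp.max()
        soil = soil + spec.gradient_amplitude * ramp
    return soil


def _place_plants(spec: FieldSpec, rng, soil, proximity: float | None = None):
    """Render and position every plant; returns image, per-plant masks."""
    h, w = spec.height, spec.width
    img = soil.copy()
    occupied = np.zeros((h, w), dtype=bool)
    plant_masks: list[np.ndarray] = []
    plant_info: list[dict] = []

    n_crop = int(round(spec.n_plants * spec.crop_fraction))
    classes = [CROP] * n_crop + [WEED] * (spec.n_plants - n_crop)
    rng.shuffle(classes)

    crop_centers: list[tuple[int, int]] = []
    for p_idx, cls in enumerate(classes):
        contrast = rng.uniform(*spec.contrast)
        target_area = rng.uniform(*spec.area)
        cov, half = _render_plant(cls, target_area, rng)
        margin = half + spec.placement_margin
        if 2 * margin >= min(h, w):
            raise ValueError("plants cannot be placed without exceeding the image")

        overlap_target = None
        if (cls == WEED and crop_centers
                and rng.uniform() < spec.overlap_probability):
            overlap_target = crop_centers[int(rng.integers(len(crop_centers)))]

        placed = False
        for _ in range(300):
            if overlap_target is not None:
                cy = int(np.clip(overlap_target[0] + rng.integers(-half // 2, half // 2 + 1),
                                 margin, h - margin - 1))
                cx = int(np.clip(overlap_target[1] + rng.integers(-half // 2, half // 2 + 1),
                                 margin, w - margin - 1))
            elif proximity is not None:
                cy = int(rng.integers(int(h / 2 - proximity), int(h / 2 + proximity)))
                cx = int(rng.integers(int(w / 2 - proximity), int(w / 2 + proximity)))
                cy = int(np.clip(cy, margin, h - margin - 1))
                cx = int(np.clip(cx, margin, w - margin - 1))
            else:
                cy = int(rng.integers(margin, h - margin))
                cx = int(rng.integers(margin, w - margin))
            sl = (slice(cy - half, cy + half + 1), slice(cx - half, cx + half + 1))
            overlaps = occupied[sl][cov > 0].any()
            if overlaps and overlap_target is None and proximity is None:
                continue
            placed = True
            break
        if not placed:
            raise ValueError("plants cannot be placed without exceeding the image")

        level = soil[cy, cx] + contrast
        local = img[sl]
        lifted = soil[sl] + cov * (level - soil[sl])
        img[sl] = np.maximum(local, lifted)
        mask = np.zeros((h, w), dtype=bool)
        mask[sl] = cov >= 0.5
        plant_masks.append(mask)
        grown = ndimage.binary_dilation(cov > 0, iterations=2)
        occupied[sl] |= grown
        if cls == CROP:
            crop_centers.append((cy, cx))
        plant_info.append(dict(plant_id=p_idx, **{"class": cls},
                               row=cy, col=cx, contrast=contrast,
                               area=int(mask.sum())))
    return img, plant_masks, plant_info


def _speckle(spec: FieldSpec, rng, img, keepout):
    h, w = img.shape
    n = int(round(spec.speckle_rate * h * w))
    if n == 0:
        return img
    free = np.flatnonzero(~keepout.ravel())
    if free.size == 0:
        return img
    chosen = rng.choice(free, size=min(n, free.size), replace=False)
    amps = rng.uniform(*spec.speckle_amplitude, size=chosen.size)
    flat = img.ravel()
    flat[chosen] = flat[chosen] + amps
    return flat.reshape(h, w)


def generate_field(spec: FieldSpec | None = None, *,
                   _proximity: float | None = None) -> FieldSample:
    """Generate one field; bit-identical for identical spec (incl. seed)."""
    spec = spec or FieldSpec()
    rng = np.random.default_rng(spec.seed)
    soil = _soil(spec, rng)
    img, plant_masks, plant_info = _place_plants(spec, rng, soil,
                                                 proximity=_proximity)
    if plant_masks:
        truth = np.logical_or.reduce(plant_masks)
        near_plants = ndimage.binary_dilation(
            np.logical_or.reduce([m for m in plant_masks]) | (img > soil + 1),
            iterations=2,
        )
    else:
        truth = np.zeros((spec.height, spec.width), dtype=bool)
        near_plants = np.zeros_like(truth)
    img = _speckle(spec, rng, img, keepout=near_plants)

    values = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    ndvi = NDVIImage(values=values, computed=False)

    label_map, n_regions = ndimage.label(truth, structure=np.ones((3, 3)))
    records = []
    for rid in range(1, n_regions + 1):
        region = label_map == rid
        classes = {info["class"]
                   for info, mask in zip(plant_info, plant_masks)
                   if (mask & region).any()}
        cls = MIXED if len(classes) > 1 else classes.pop()
        records.append(dict(region_id=rid, **{"class": cls},
                            area=int(region.sum())))
    region_table = pd.DataFrame(records,
                                columns=["region_id", "class", "area"])
    plant_table = pd.DataFrame(plant_info,
                               columns=["plant_id", "class", "row", "col",
                                        "contrast", "area"])
    return FieldSample(ndvi=ndvi, truth=BinaryMask(values=truth),
                       label_map=label_map.astype(np.int32),
                       region_table=region_table, plant_table=plant_table,
                       spec=spec)


def generate_lowveg(spec: FieldSpec | None = None) -> FieldSample:
    """Low-vegetation variant: few small plants, <= 0.5% foreground.

    Mirrors a near-empty field under natural (uncontrolled) lighting:
    4 plants in close proximity whose total area stays below half a percent
    of the image, with a pronounced illumination drift (25 grey levels, vs 8
    for regular fields).  This is the regime in which a global threshold
    either splits the soil itself or is not well-defined, while the local
    max-tree decision is unaffected.
    """
    spec = spec or FieldSpec()
    budget = 0.005 * spec.height * spec.width
    n = min(spec.n_plants, 4) or 4
    per_plant = 0.8 * budget / n
    lo = min(spec.area[0], per_plant * 0.8)
    hi = min(spec.area[1], per_plant)
    low_spec = replace(spec, n_plants=n, area=(lo, hi),
                       gradient_amplitude=max(spec.gradient_amplitude, 25.0))
    sample = generate_field(low_spec, _proximity=min(spec.height, spec.width) / 6)
    fraction = sample.truth.values.mean()
    if fraction > 0.005:
        raise ValueError(f"foreground fraction {fraction:.4f} exceeds 0.5%")
    return sample


def generate_toy_binary() -> np.ndarray:
    """Small binary scene for morphology oracles (cf. area opening).

    Exactly three connected components: a blocky object with fine boundary
    detail (area >= 9), a thin elongated object (area >= 9), and an object
    smaller than 9 px, so an area opening at threshold 9 removes exactly one.
    """
    img = np.zeros((16, 20), dtype=bool)
    # Blocky object with notched boundary, area 30.
    img[2:8, 2:8] = True
    img[2, 2] = img[3, 7] = img[7, 4] = False
    img[4:6, 8] = True
    img[2:8, 5] &= True
    # Thin elongated object, area 12.
    img[11, 4:16] = True
    # Small object, area 4 (< 9).
    img[13:15, 17:19] = True
    return img


def generate_region_dataset(n_images: int, spec: FieldSpec | None = None,
                            seed: int = 0) -> pd.DataFrame:
    """Labelled per-region feature table pooled over ``n_images`` fields.

    Each image is generated with a distinct seed derived from ``seed``; the
    result is ready for the image-level cross-validation protocol.
    """
    spec = spec or FieldSpec()
    frames = []
    for i in range(n_images):
        sample = generate_field(replace(spec, seed=seed * 100003 + i))
        frames.append(sample.feature_table(image_id=i))
    return pd.concat(frames, ignore_index=True)
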