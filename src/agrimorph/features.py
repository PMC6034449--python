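"""Per-region shape and contrast descriptors, and feature-matrix assembly.

Five descriptors per region, all computable incrementally on the max-tree
(perimeter-based measures are deliberately avoided — the perimeter is neither
increasing nor incrementally computable on nested regions):

solidity
    area over convex-hull area, the hull taken over the four corner points of
    every member pixel (a 1-pixel-wide region still has hull area).
eccentricity
    of the equivalent ellipse with the region's second-order central moments:
    sqrt(1 - b^2/a^2) from the eigenvalues of the moment matrix.
circularity
    moment-based, perimeter-free:  A^2 / (2 pi (mu20 + mu02 + A/6)); equal to
    1 for an ideal disk, smaller otherwise.  The A/6 term is the discrete
    per-pixel correction for moments taken at pixel centers.
non-compactness
    Hu's first moment invariant with the same discrete correction:
    2 pi ((mu20 + mu02)/A^2 + 1/(6 A)); 1 for an ideal disk, larger for
    elongated shapes.  Exact reciprocal of circularity as implemented.
grey range
    f_max - f_min over the region's pixels on the NDVI image — the only
    grey-level-dependent feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maxtree import (
    MaxTree,
    NodeAttributes,
    node_pixel_set,
    region_hull_area,
)

__all__ = [
    "RegionFeatures",
    "FEATURE_NAMES",
    "solidity",
    "eccentricity",
    "circularity",
    "non_compactness",
    "grey_range",
    "region_features",
    "features_from_pixels",
    "build_feature_matrix",
    "FeatureNormalizer",
]

FEATURE_NAMES = ("solidity", "eccentricity", "circularity",
                 "non_compactness", "grey_range")


@dataclass(frozen=True)
class RegionFeatures:
    solidity: float
    eccentricity: float
    circularity: float
    non_compactness: float
    grey_range: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def _moments(area: float, sum_x, sum_y, sum_xx, sum_yy, sum_xy):
    mu20 = sum_xx - sum_x**2 / area
    mu02 = sum_yy - sum_y**2 / area
    mu11 = sum_xy - sum_x * sum_y / area
    return mu20, mu02, mu11


def solidity(area: float, hull_area: float) -> float:
    if hull_area <= 0:
        raise ValueError("degenerate convex hull")
    return float(area / hull_area)


def eccentricity(area: float, mu20: float, mu02: float, mu11: float) -> float:
    """sqrt(1 - b^2/a^2) of the equivalent ellipse; 0 for a single pixel."""
    m = np.array([[mu20, mu11], [mu11, mu02]]) / area
    lam2, lam1 = np.linalg.eigvalsh(m)  # ascending
    if lam1 <= 0:
        return 0.0
    lam2 = max(lam2, 0.0)
    return float(np.sqrt(1.0 - lam2 / lam1))


def circularity(area: float, mu20: float, mu02: float) -> float:
    return float(area**2 / (2.0 * np.pi * (mu20 + mu02 + area / 6.0)))


def non_compactness(area: float, mu20: float, mu02: float) -> float:
    i_r = mu20 + mu02
    return float(2.0 * np.pi * (i_r / area**2 + 1.0 / (6.0 * area)))


def grey_range(f_max: float, f_min: float) -> float:
    return float(abs(f_max - f_min))


def region_features(tree: MaxTree, attrs: NodeAttributes, node: int
                    ) -> RegionFeatures:
    """Features of one tree node from its propagated attributes.

    The convex hull uses the propagated hull points when available and falls
    back to the region's explicit pixel set otherwise.
    """
    tree._check_node(node)
    area = float(attrs.area[node])
    mu20, mu02, mu11 = (m[node] for m in attrs.central_moments())
    if attrs._hull_area is not None:
        h_area = attrs.hull_area(node)
    else:
        h_area = region_hull_area(*node_pixel_set(tree, node))
    return RegionFeatures(
        solidity=solidity(area, h_area),
        eccentricity=eccentricity(area, mu20, mu02, mu11),
        circularity=circularity(area, mu20, mu02),
        non_compactness=non_compactness(area, mu20, mu02),
        grey_range=grey_range(float(attrs.f_max[node]), float(attrs.f_min[node])),
    )


def features_from_pixels(rows, cols, values) -> RegionFeatures:
    """Features computed directly from an explicit pixel set.

    Reference (non-incremental) route: moments summed over pixel-center
    coordinates, hull over pixel corners, extrema over the supplied grey
    values.  Equals the incremental route within numerical tolerance.
    """
    rows = np.asarray(rows, dtype=np.float64)
    cols = np.asarray(cols, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if rows.size == 0:
        raise ValueError("empty pixel set")
    area = float(rows.size)
    x, y = cols, rows
    mu20, mu02, mu11 = _moments(
        area, x.sum(), y.sum(), (x * x).sum(), (y * y).sum(), (x * y).sum()
    )
    h_area = region_hull_area(rows, cols)
    return RegionFeatures(
        solidity=solidity(area, h_area),
        eccentricity=eccentricity(area, mu20, mu02, mu11),
        circularity=circularity(area, mu20, mu02),
        non_compactness=non_compactness(area, mu20, mu02),
        grey_range=grey_range(values.max(), values.min()),
    )


def build_feature_matrix(features: list[RegionFeatures],
                         region_ids=None, labels=None,
                         image_ids=None) -> pd.DataFrame:
    """Stack per-region descriptors into a raw (un-normalized) feature table."""
    if not features:
        raise ValueError("no regions supplied")
    frame = pd.DataFrame([f.as_array() for f in features],
                         columns=list(FEATURE_NAMES))
    if region_ids is not None:
        frame.insert(0, "region_id", list(region_ids))
    if image_ids is not None:
        frame.insert(0, "image_id", list(image_ids))
    if labels is not None:
        frame["label"] = list(labels)
    return frame


class FeatureNormalizer:
    """Min-max normalization to [0, 1] with dataset statistics.

    Statistics are learned on the training data only (``fit``); applying them
    to unseen rows can exceed [0, 1], so transformed values are clipped.
    A constant column maps to 0.5 by convention.  Compatible with sklearn
    pipelines (fit/transform/get_params).
    """

    def __init__(self, clip: bool = True):
        self.clip = clip

    def get_params(self, deep: bool = True) -> dict:
        return {"clip": self.clip}

    def set_params(self, **params) -> "FeatureNormalizer":
        for k, v in params.items():
            if k != "clip":
                raise ValueError(f"unknown parameter {k!r}")
            self.clip = v
        return self

    def fit(self, X, y=None) -> "FeatureNormalizer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("expected a non-empty 2-D feature matrix")
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        self.scale_ = self.max_ - self.min_
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "min_"):
            raise ValueError("normalizer is not fitted")
        X = np.asarray(X, dtype=np.float64)
        constant = self.scale_ == 0
        scale = np.where(constant, 1.0, self.scale_)
        out = (X - self.min_) / scale
        out[:, constant] = 0.5
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
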