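"""Growth-factor (stability) segmentation on max-tree branches.

Walking a branch from a marker leaf toward the root visits every region
obtained by thresholding the image around that maximum with a decreasing
threshold.  A locally contrasted object shows a stable area over a span of
grey levels and then grows abruptly when it merges into its background; the
growth factor

    G(R_k) = (A(R at level k - delta) - A(R_k)) / A(R_k)

over a span of ``delta`` grey levels spikes at that merge.  The candidate
with the largest growth is then adjusted to favour slightly larger, repeated
regions (MSER-style stability): candidates with lower but still significant
growth whose area exceeds the current best by a factor ``k_factor`` are
adopted when a run of ``l_run`` consecutive candidates of similar area
(relative tolerance ``e_area``) confirms them.

The accepted regions from all marker branches are deduplicated by node
identity (nested, non-identical regions are kept) and optionally filtered by
a minimal area ``area_threshold``, which takes the place of post-processing
noise removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .extinction import MarkerSet, grey_range_extinction, select_markers
from .io import BinaryMask, NDVIImage
from .maxtree import MaxTree, build_max_tree, node_mask, node_pixel_set

__all__ = [
    "SegmentationParams",
    "RegionCandidate",
    "AcceptedRegion",
    "SegmentationResult",
    "branch_of",
    "growth_factors",
    "growth_factor",
    "select_region_on_branch",
    "segment",
    "segment_tree",
    "result_to_mask",
    "MaxTreeSegmenter",
]


@dataclass
class SegmentationParams:
    """Tunable parameters of the stability segmentation.

    delta : grey-level span over which growth is measured (default 30)
    g_min : minimal allowed growth for a candidate (default 10)
    k_factor : size factor a larger replacement candidate must exceed (15)
    e_area : relative area tolerance for "similar" regions (0.15)
    l_run : minimal number of similar consecutive regions (6)
    area_threshold : minimal accepted region area in pixels, 0 = disabled
    min_extinction : marker contrast threshold in grey levels (10)
    connectivity : pixel connectivity of the foreground tree (4)
    """

    delta: int = 30
    g_min: float = 10.0
    k_factor: float = 15.0
    e_area: float = 0.15
    l_run: int = 6
    area_threshold: int = 0
    min_extinction: int = 10
    connectivity: int = 4

    def __post_init__(self):
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.g_min < 0:
            raise ValueError("g_min must be >= 0")
        if self.k_factor < 1:
            raise ValueError("k_factor must be >= 1")
        if not (0 <= self.e_area < 1):
            raise ValueError("e_area must lie in [0, 1)")
        if self.l_run < 1:
            raise ValueError("l_run must be >= 1")
        if self.area_threshold < 0:
            raise ValueError("area_threshold must be >= 0")


@dataclass(frozen=True)
class RegionCandidate:
    """A branch region: tree node with its level, area and growth factor."""

    node: int
    level: int
    area: int
    growth: float = np.nan


@dataclass(frozen=True)
class AcceptedRegion:
    node: int
    level: int
    area: int
    growth: float
    marker_leaf: int
    marker_pixel: int


@dataclass
class SegmentationResult:
    """Accepted (possibly nested) regions plus provenance.

    Pixel sets are materialized lazily from the tree; regions are unique by
    tree node, every region satisfies the area threshold when enabled.
    """

    regions: list[AcceptedRegion]
    params: SegmentationParams
    tree: MaxTree = field(repr=False)
    n_markers: int = 0
    n_leaves: int = 0

    def __len__(self) -> int:
        return len(self.regions)

    def pixel_set(self, i: int):
        return node_pixel_set(self.tree, self.regions[i].node)

    def to_mask(self) -> BinaryMask:
        out = np.zeros(self.tree.shape, dtype=bool)
        for reg in self.regions:
            out |= node_mask(self.tree, reg.node)
        return BinaryMask(values=out)

    def to_label_image(self) -> np.ndarray:
        """16-bit label image; nested regions overwrite outer ones.

        Regions are drawn largest-first so inner (later-accepted, smaller)
        regions remain visible.
        """
        out = np.zeros(self.tree.shape, dtype=np.uint16)
        order = sorted(range(len(self.regions)),
                       key=lambda i: -self.regions[i].area)
        for rank, i in enumerate(order):
            out[node_mask(self.tree, self.regions[i].node)] = i + 1
        return out

    def to_dataframe(self):
        import pandas as pd

        records = []
        for i, reg in enumerate(self.regions):
            r, c = np.unravel_index(reg.marker_pixel, self.tree.shape)
            records.append(
                dict(region=i + 1, node=reg.node, marker_row=int(r),
                     marker_col=int(c), level=reg.level, area=reg.area,
                     growth=reg.growth)
            )
        return pd.DataFrame(
            records,
            columns=["region", "node", "marker_row", "marker_col",
                     "level", "area", "growth"],
        )


def branch_of(tree: MaxTree, leaf: int) -> list[RegionCandidate]:
    """Regions along the leaf-to-root branch, by strictly decreasing level."""
    tree._check_node(leaf)
    if not tree.is_leaf()[leaf]:
        raise ValueError(f"node {leaf} is not a leaf")
    nodes = []
    node = int(leaf)
    while True:
        nodes.append(node)
        parent = int(tree.parent[node])
        if parent == node:
            break
        node = parent
    return [
        RegionCandidate(node=n, level=int(tree.level[n]),
                        area=int(tree.area[n]))
        for n in nodes
    ]


def growth_factors(branch: list[RegionCandidate], delta: int
                   ) -> list[RegionCandidate]:
    """Annotate every branch candidate with its growth factor.

    The comparison region for a candidate at level ``k`` is the branch
    region reached ``delta`` grey levels toward the root: the candidate with
    the largest level <= ``k - delta``.  A node's growth is thus measured
    against everything its component merges with within the ``delta`` span
    below its own level — a node that directly absorbs a much darker
    background registers the spike even when the canonical tree skips the
    intermediate levels.  When no candidate lies ``delta`` levels down
    (the span runs past the root level) the root's area is used.
    """
    levels = np.array([c.level for c in branch])        # strictly decreasing
    areas = np.array([c.area for c in branch], dtype=np.float64)
    asc = levels[::-1]                                  # ascending for search
    out = []
    for c in branch:
        target = c.level - delta
        pos = np.searchsorted(asc, target, side="right") - 1
        ref_area = areas[len(branch) - 1 - pos] if pos >= 0 else areas[-1]
        growth = (ref_area - c.area) / c.area
        out.append(RegionCandidate(node=c.node, level=c.level, area=c.area,
                                   growth=float(growth)))
    return out


def growth_factor(branch: list[RegionCandidate], index: int, delta: int) -> float:
    """Growth factor of a single branch candidate (see :func:`growth_factors`)."""
    return growth_factors(branch, delta)[index].growth


def select_region_on_branch(branch: list[RegionCandidate],
                            params: SegmentationParams
                            ) -> RegionCandidate | None:
    """Pick the branch region by maximal growth with the four-step adjustment.

    Starting from the candidate B with the largest growth (ties prefer the
    higher level, i.e. the more contrasted core):

    1. examine candidates R with ``g_min < G(R) < G(B)`` in descending-growth
       order (ties again by descending level),
    2. take the first with ``A(R) > k_factor * A(B)``,
    3. count the consecutive candidates that follow R in that order whose
       area lies within ``e_area`` relative tolerance of ``A(R)``,
    4. if the count reaches ``l_run``, adopt R as the new B and restart.

    Returns None when no candidate exceeds ``g_min``.
    """
    cands = [c for c in branch if np.isfinite(c.growth)]
    if not cands:
        return None
    order = sorted(cands, key=lambda c: (-c.growth, -c.level))
    best = order[0]
    if best.growth <= params.g_min:
        return None

    while True:
        eligible = [c for c in order
                    if params.g_min < c.growth < best.growth]
        replacement = None
        for pos, cand in enumerate(eligible):
            if cand.area > params.k_factor * best.area:
                replacement = (pos, cand)
                break
        if replacement is None:
            return best
        pos, cand = replacement
        lo = (1 - params.e_area) * cand.area
        hi = (1 + params.e_area) * cand.area
        similar = 0
        for follower in eligible[pos + 1:]:
            if lo <= follower.area <= hi:
                similar += 1
                if similar >= params.l_run:
                    break
            else:
                break
        if similar >= params.l_run:
            best = cand
        else:
            return best


def segment_tree(tree: MaxTree, params: SegmentationParams | None = None,
                 extinction: dict[int, int] | None = None,
                 markers: MarkerSet | None = None) -> SegmentationResult:
    """Run marker selection and branch-wise region selection on a built tree.

    Precomputed extinction values or markers may be passed to amortize the
    tree across parameter sweeps (e.g. varying ``delta``).
    """
    params = params or SegmentationParams()
    if markers is None:
        if extinction is None:
            extinction = grey_range_extinction(tree)
        markers = select_markers(tree, extinction,
                                 min_extinction=params.min_extinction)
    accepted: list[AcceptedRegion] = []
    seen_nodes: set[int] = set()
    for leaf, pixel in zip(markers.leaves, markers.pixel):
        branch = growth_factors(branch_of(tree, int(leaf)), params.delta)
        chosen = select_region_on_branch(branch, params)
        if chosen is None:
            continue
        if params.area_threshold > 0 and chosen.area < params.area_threshold:
            continue
        if chosen.node in seen_nodes:  # exact duplicates share the tree node
            continue
        seen_nodes.add(chosen.node)
        accepted.append(
            AcceptedRegion(node=chosen.node, level=chosen.level,
                           area=chosen.area, growth=chosen.growth,
                           marker_leaf=int(leaf), marker_pixel=int(pixel))
        )
    return SegmentationResult(
        regions=accepted, params=params, tree=tree,
        n_markers=len(markers), n_leaves=int(tree.is_leaf().sum()),
    )


def segment(image, params: SegmentationParams | None = None
            ) -> SegmentationResult:
    """Full stability segmentation of an 8-bit NDVI image."""
    params = params or SegmentationParams()
    arr = image.values if isinstance(image, NDVIImage) else image
    tree = build_max_tree(arr, connectivity=params.connectivity)
    return segment_tree(tree, params)


def result_to_mask(result: SegmentationResult, shape=None) -> BinaryMask:
    """Union of all accepted regions' pixel sets as a binary mask."""
    mask = result.to_mask()
    if shape is not None and tuple(shape) != mask.shape:
        raise ValueError("requested shape does not match the segmented image")
    return mask


class MaxTreeSegmenter:
    """Estimator-style wrapper around :func:`segment`.

    Carries the segmentation parameters with sklearn-style
    ``get_params``/``set_params`` so the segmenter can be configured and
    cloned like an estimator; ``predict`` returns the boolean vegetation mask
    of a single image.
    """

    def __init__(self, delta: int = 30, g_min: float = 10.0,
                 k_factor: float = 15.0, e_area: float = 0.15, l_run: int = 6,
                 area_threshold: int = 0, min_extinction: int = 10,
                 connectivity: int = 4):
        self.delta = delta
        self.g_min = g_min
        self.k_factor = k_factor
        self.e_area = e_area
        self.l_run = l_run
        self.area_threshold = area_threshold
        self.min_extinction = min_extinction
        self.connectivity = connectivity

    _param_names = ("delta", "g_min", "k_factor", "e_area", "l_run",
                    "area_threshold", "min_extinction", "connectivity")

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "MaxTreeSegmenter":
        for name, value in params.items():
            if name not in self._param_names:
                raise ValueError(f"unknown parameter {name!r}")
            setattr(self, name, value)
        return self

    def to_segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(**self.get_params())

    def fit(self, X=None, y=None) -> "MaxTreeSegmenter":
        return self  # stateless: parameters fully define the behaviour

    def segment(self, image) -> SegmentationResult:
        return segment(image, self.to_segmentation_params())

    def predict(self, image) -> np.ndarray:
        return self.segment(image).to_mask().values
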