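"""Canonical max-tree / min-tree with incremental node attributes.

The max-tree represents a grey image by the nesting of the connected
components (peak components) of its upper level sets ``L_k = {f >= k}``.
Every node owns the "proper" pixels whose value equals the node level; the
full pixel set of a node is its proper pixels plus those of all descendants
and is a connected component of ``L_k`` at the node's level.  Leaves are the
regional maxima of the image.  Components that are identical across
consecutive levels are stored once, at their highest level (canonical
representation).

Construction delegates the parent/traverser computation to
``skimage.morphology.max_tree`` and canonicalizes the per-pixel parent
pointers into a compact node table (root is node 0; every parent id is
smaller than its children's, i.e. node ids are in topological order).

Attributes (area, raw coordinate sums for moments up to order two, grey
extrema, convex-hull vertices) are propagated leaves-to-root so that every
pixel is visited once, which is what makes per-region feature computation on
the full hierarchy affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from skimage.morphology import max_tree as _skimage_max_tree

from .io import NDVIImage

__all__ = [
    "MaxTree",
    "NodeAttributes",
    "build_max_tree",
    "build_min_tree",
    "compute_attributes",
    "node_pixel_set",
    "area_opening",
]


def _as_grey(image) -> np.ndarray:
    if isinstance(image, NDVIImage):
        image = image.values
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("expected an integer-valued image")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("grey levels must lie in [0, 255]")
    return arr.astype(np.uint8, copy=False)


def _union_find_max_tree(image: np.ndarray, connectivity: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Union-find max-tree construction (parent pixels + root-first order).

    Pixels are processed by decreasing value (ties by raster order) and
    merged with already-processed neighbours, so every parent pointer leads
    to an equal-or-lower value and the reversed processing order is a valid
    root-first traverser.
    """
    h, w = image.shape
    flat = image.ravel()
    n = flat.size
    order = np.lexsort((np.arange(n), -flat.astype(np.int64)))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    if connectivity == 4:
        steps = ((-1, 0), (1, 0), (0, -1), (0, 1))
    else:
        steps = tuple((dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                      if (dy, dx) != (0, 0))

    parent = np.arange(n, dtype=np.int64)
    zpar = np.arange(n, dtype=np.int64)
    processed = np.zeros(n, dtype=bool)

    def find(i: int) -> int:
        root = i
        while zpar[root] != root:
            root = zpar[root]
        while zpar[i] != root:
            zpar[i], i = root, zpar[i]
        return root

    for p in order:
        processed[p] = True
        py, px = divmod(int(p), w)
        for dy, dx in steps:
            ny, nx = py + dy, px + dx
            if 0 <= ny < h and 0 <= nx < w:
                q = ny * w + nx
                if processed[q]:
                    r = find(q)
                    if r != p:
                        parent[r] = p
                        zpar[r] = p
    return parent, order[::-1].copy()


class MaxTree:
    """Canonical component tree of an 8-bit image.

    Parameters are not meant to be passed directly; use :func:`build_max_tree`
    or :func:`build_min_tree`.

    Attributes
    ----------
    image : ndarray
        The grey image the tree decomposes (already inverted for a min-tree).
    level : ndarray of shape (n_nodes,)
        Grey level of each node on the working image.
    parent : ndarray of shape (n_nodes,)
        Parent node id; ``parent[0] == 0`` (the root points to itself).
    node_of_pixel : ndarray of shape (n_pixels,)
        Owning node of each raveled pixel (the node whose level equals the
        pixel value).
    area : ndarray of shape (n_nodes,)
        Pixel count of each node's full pixel set.
    inverted : bool
        True for a min-tree (built on ``255 - f``); :attr:`original_level`
        then reports levels on the original scale.
    """

    def __init__(self, image: np.ndarray, connectivity: int = 4,
                 inverted: bool = False):
        if connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        self.image = _as_grey(image)
        self.connectivity = connectivity
        self.inverted = inverted
        self.shape = self.image.shape

        if min(self.shape) > 1:
            parent_px, traverser = _skimage_max_tree(
                self.image, connectivity=1 if connectivity == 4 else 2
            )
        else:
            # skimage's max_tree rejects singleton dimensions; fall back to a
            # small union-find construction for 1-pixel-thick images.
            parent_px, traverser = _union_find_max_tree(
                self.image, connectivity
            )
        flat = self.image.ravel()
        parent_px = parent_px.ravel()
        root_px = traverser[0]

        canonical = flat != flat[parent_px]
        canonical[root_px] = True

        # Resolve each pixel's canonical representative by pointer doubling:
        # canonical pixels point to themselves, others to their parent pixel.
        n_px = flat.size
        idx = np.arange(n_px)
        ptr = np.where(canonical, idx, parent_px)
        while True:
            nxt = ptr[ptr]
            if np.array_equal(nxt, ptr):
                break
            ptr = nxt

        # Node ids in traverser (topological) order -> parent id < child id.
        canon_in_order = traverser[canonical[traverser]]
        n_nodes = canon_in_order.size
        node_id_of_canon = np.empty(n_px, dtype=np.int64)
        node_id_of_canon[canon_in_order] = np.arange(n_nodes)

        self.node_of_pixel = node_id_of_canon[ptr]
        self.level = flat[canon_in_order].astype(np.int64)
        self.parent = node_id_of_canon[ptr[parent_px[canon_in_order]]]
        self.root = 0
        self._canon_pixel = canon_in_order  # a proper pixel of each node

        # Depth of every node; parent ids are topological so one ascending
        # pass suffices (depth is bounded by the 256 grey levels anyway).
        depth = np.zeros(n_nodes, dtype=np.int64)
        par = self.parent
        for i in range(1, n_nodes):
            depth[i] = depth[par[i]] + 1
        self.depth = depth
        self._depth_groups = None

        self.area = self._accumulate_sum(
            np.bincount(self.node_of_pixel, minlength=n_nodes).astype(np.int64)
        )

    # -- tree-structure helpers -------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.level.size

    def _groups_by_depth(self):
        if self._depth_groups is None:
            maxd = int(self.depth.max()) if self.n_nodes else 0
            groups = [None] * (maxd + 1)
            order = np.argsort(self.depth, kind="stable")
            bounds = np.searchsorted(self.depth[order], np.arange(maxd + 2))
            for d in range(maxd + 1):
                groups[d] = order[bounds[d]:bounds[d + 1]]
            self._depth_groups = groups
        return self._depth_groups

    def _accumulate_sum(self, values: np.ndarray) -> np.ndarray:
        """Add each node's value into all its ancestors (subtree sums)."""
        out = np.array(values, copy=True)
        for group in reversed(self._groups_by_depth()[1:]):
            np.add.at(out, self.parent[group], out[group])
        return out

    def _accumulate_max(self, values: np.ndarray) -> np.ndarray:
        out = np.array(values, copy=True)
        for group in reversed(self._groups_by_depth()[1:]):
            np.maximum.at(out, self.parent[group], out[group])
        return out

    def _accumulate_min(self, values: np.ndarray) -> np.ndarray:
        out = np.array(values, copy=True)
        for group in reversed(self._groups_by_depth()[1:]):
            np.minimum.at(out, self.parent[group], out[group])
        return out

    def is_leaf(self) -> np.ndarray:
        """Boolean array marking nodes without children (regional maxima)."""
        out = np.ones(self.n_nodes, dtype=bool)
        out[self.parent[1:]] = False
        return out

    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.is_leaf())

    def children_lists(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            kids[self.parent[i]].append(i)
        return kids

    def proper_pixels(self, node: int) -> np.ndarray:
        """Raveled indices of the pixels owned directly by ``node``."""
        self._check_node(node)
        return np.flatnonzero(self.node_of_pixel == node)

    def descendants_mask(self, node: int) -> np.ndarray:
        """Boolean array over nodes: node itself plus all descendants."""
        self._check_node(node)
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[node] = True
        for group in self._groups_by_depth()[1:]:
            mask[group] |= mask[self.parent[group]]
        return mask

    def reconstruct(self) -> np.ndarray:
        """Image whose pixels take the level of their owning node.

        Equals the input image exactly (a structural invariant).
        """
        levels = self.level
        if self.inverted:
            levels = 255 - levels
        return levels[self.node_of_pixel].reshape(self.shape).astype(np.uint8)

    @property
    def original_level(self) -> np.ndarray:
        """Node levels on the original image scale (min-tree aware)."""
        return 255 - self.level if self.inverted else self.level

    def _check_node(self, node: int) -> None:
        if not (0 <= int(node) < self.n_nodes):
            raise IndexError(f"invalid node id {node}")

    def to_dataframe(self, attributes: "NodeAttributes | None" = None):
        """Node table (id, parent, level, area, and attributes) for export."""
        import pandas as pd

        data = {
            "node": np.arange(self.n_nodes),
            "parent": self.parent,
            "level": self.original_level,
            "area": self.area,
        }
        if attributes is not None:
            mu20, mu02, mu11 = attributes.central_moments()
            data.update(
                f_min=attributes.f_min,
                f_max=attributes.f_max,
                mu20=mu20,
                mu02=mu02,
                mu11=mu11,
            )
        return pd.DataFrame(data)


@dataclass
class NodeAttributes:
    """Per-node incremental attributes, propagated leaves-to-root.

    Raw sums are over pixel-center coordinates (x = column, y = row); the
    discrete per-pixel corrections used by the shape features are applied in
    the feature formulas, not here.  ``hull_points`` (optional) holds for
    each node the vertices of the convex hull of the four corner points of
    every member pixel, so a 1-pixel-wide region still has nonzero hull area.
    """

    area: np.ndarray
    sum_x: np.ndarray
    sum_y: np.ndarray
    sum_xx: np.ndarray
    sum_yy: np.ndarray
    sum_xy: np.ndarray
    f_min: np.ndarray
    f_max: np.ndarray
    hull_points: list | None = None
    _hull_area: np.ndarray | None = field(default=None, repr=False)

    def central_moments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mu20, mu02, mu11) about each node's centroid, pixel centers."""
        a = self.area.astype(np.float64)
        mu20 = self.sum_xx - self.sum_x**2 / a
        mu02 = self.sum_yy - self.sum_y**2 / a
        mu11 = self.sum_xy - self.sum_x * self.sum_y / a
        return mu20, mu02, mu11

    def hull_area(self, node: int) -> float:
        if self._hull_area is None:
            raise ValueError("hull attributes were not computed")
        return float(self._hull_area[node])

    @property
    def grey_range(self) -> np.ndarray:
        return self.f_max - self.f_min


def build_max_tree(image, connectivity: int = 4) -> MaxTree:
    """Build the canonical max-tree of an 8-bit image.

    Leaves correspond one-to-one with the regional maxima of the image under
    the chosen connectivity (4 by default).
    """
    return MaxTree(image, connectivity=connectivity, inverted=False)


def build_min_tree(image, connectivity: int = 4) -> MaxTree:
    """Dual tree built from lower level sets: max-tree of ``255 - f``.

    ``tree.original_level`` reports node levels on the original scale.
    """
    arr = _as_grey(image.values if isinstance(image, NDVIImage) else image)
    return MaxTree(255 - arr, connectivity=connectivity, inverted=True)


def pixel_corners(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Four corner points (x, y) of each pixel treated as a unit square."""
    x = cols.astype(np.float64)
    y = rows.astype(np.float64)
    return np.concatenate(
        [
            np.column_stack([x - 0.5, y - 0.5]),
            np.column_stack([x + 0.5, y - 0.5]),
            np.column_stack([x - 0.5, y + 0.5]),
            np.column_stack([x + 0.5, y + 0.5]),
        ]
    )


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    # Corner-point sets are never collinear (each pixel spans a unit square).
    hull = ConvexHull(points)
    return points[hull.vertices]


def compute_attributes(tree: MaxTree, image=None, with_hull: bool = False
                       ) -> NodeAttributes:
    """Propagate area, moment sums, grey extrema (and optionally hulls).

    ``image`` defaults to the tree's own working image; passing a different
    array (e.g. original values for a min-tree) is allowed as long as the
    shape matches.  Convex-hull propagation visits candidate vertices only
    (child hull vertices plus own proper-pixel corners) and is intended for
    the small-to-medium trees on which per-node hulls are actually needed;
    features of individual segmented regions use the per-region hull route.
    """
    if image is None:
        image = tree.image
    else:
        image = image.values if isinstance(image, NDVIImage) else np.asarray(image)
        if image.shape != tree.shape:
            raise ValueError("attribute image shape does not match the tree")

    n = tree.n_nodes
    flat = image.ravel().astype(np.int64)
    npx = flat.size
    rows, cols = np.unravel_index(np.arange(npx), tree.shape)
    x = cols.astype(np.float64)
    y = rows.astype(np.float64)
    owner = tree.node_of_pixel

    def node_sum(vals):
        return tree._accumulate_sum(
            np.bincount(owner, weights=vals, minlength=n)
        )

    area = tree.area.astype(np.int64)
    sum_x = node_sum(x)
    sum_y = node_sum(y)
    sum_xx = node_sum(x * x)
    sum_yy = node_sum(y * y)
    sum_xy = node_sum(x * y)

    fmin_own = np.full(n, np.iinfo(np.int64).max)
    fmax_own = np.full(n, np.iinfo(np.int64).min)
    np.minimum.at(fmin_own, owner, flat)
    np.maximum.at(fmax_own, owner, flat)
    f_min = tree._accumulate_min(fmin_own)
    f_max = tree._accumulate_max(fmax_own)

    attrs = NodeAttributes(
        area=area, sum_x=sum_x, sum_y=sum_y, sum_xx=sum_xx, sum_yy=sum_yy,
        sum_xy=sum_xy, f_min=f_min, f_max=f_max,
    )

    if with_hull:
        kids = tree.children_lists()
        hulls: list[np.ndarray | None] = [None] * n
        hull_area = np.zeros(n, dtype=np.float64)
        for node in range(n - 1, -1, -1):
            own = tree.proper_pixels(node)
            pts = [pixel_corners(rows[own], cols[own])] if own.size else []
            pts.extend(hulls[c] for c in kids[node])
            points = np.concatenate(pts)
            verts = _hull_vertices(points)
            hulls[node] = verts
            hull_area[node] = _polygon_area(verts)
        attrs.hull_points = hulls
        attrs._hull_area = hull_area

    return attrs


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a polygon given as ordered (x, y) vertices."""
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def region_hull_area(rows: np.ndarray, cols: np.ndarray) -> float:
    """Convex-hull area of a pixel set using the four-corner convention."""
    verts = _hull_vertices(pixel_corners(np.asarray(rows), np.asarray(cols)))
    return _polygon_area(verts)


def node_pixel_set(tree: MaxTree, node: int) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of the node's full pixel set (proper + descendants)."""
    mask = tree.descendants_mask(node)
    flat_idx = np.flatnonzero(mask[tree.node_of_pixel])
    return np.unravel_index(flat_idx, tree.shape)


def node_mask(tree: MaxTree, node: int) -> np.ndarray:
    """Boolean image of the node's full pixel set."""
    mask = tree.descendants_mask(node)
    return mask[tree.node_of_pixel].reshape(tree.shape)


def area_opening(image, t_area: int, connectivity: int = 4) -> np.ndarray:
    """Area opening via max-tree pruning.

    Each output pixel takes the highest level ``k`` such that the pixel lies
    in a connected component of the upper level set ``L_k`` with area at
    least ``t_area``; nodes smaller than the threshold collapse to their
    nearest surviving ancestor's level.  Anti-extensive and idempotent.
    """
    if t_area < 1:
        raise ValueError("t_area must be >= 1")
    tree = build_max_tree(image, connectivity=connectivity)
    out_level = tree.level.copy()
    survives = tree.area >= t_area
    # Root always maps to its own level (prunes to the global minimum).
    for group in tree._groups_by_depth()[1:]:
        fail = group[~survives[group]]
        out_level[fail] = out_level[tree.parent[fail]]
    return out_level[tree.node_of_pixel].reshape(tree.shape).astype(np.uint8)
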