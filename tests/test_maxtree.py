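import numpy as np
import pytest
from skimage.morphology import area_opening as skimage_area_opening

from agrimorph.maxtree import (
    area_opening,
    build_max_tree,
    build_min_tree,
    compute_attributes,
    node_pixel_set,
)
from oracles import hull_area_shapely, stacked_area_opening, upper_level_components


def tree_node_set(tree):
    """(level, frozen pixel set) of every node, for oracle comparison."""
    out = set()
    for node in range(tree.n_nodes):
        rows, cols = node_pixel_set(tree, node)
        out.add((int(tree.level[node]), frozenset(zip(rows.tolist(), cols.tolist()))))
    return out


class TestConstruction:
    def test_constant_image_single_node(self):
        tree = build_max_tree(np.full((5, 5), 42, dtype=np.uint8))
        assert tree.n_nodes == 1
        assert tree.level[0] == 42
        assert tree.area[0] == 25

    def test_two_disjoint_patches(self):
        img = np.zeros((6, 6), dtype=np.uint8)
        img[1:3, 1:3] = 100
        img[3, 4] = 200
        tree = build_max_tree(img)
        nodes = sorted(zip(tree.level.tolist(), tree.area.tolist()))
        assert nodes == [(0, 36), (100, 4), (200, 1)]
        assert all(tree.parent[i] == tree.root for i in range(1, 3))

    def test_ramp_chain(self):
        tree = build_max_tree(np.array([[0, 1, 2, 3]], dtype=np.uint8))
        assert sorted(tree.area.tolist()) == [1, 2, 3, 4]
        # A chain: every non-root node has exactly one child or none.
        assert tree.n_nodes == 4

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            build_max_tree(np.zeros((0, 0), dtype=np.uint8))

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValueError):
            build_max_tree(np.zeros((3, 3), dtype=np.uint8), connectivity=6)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_level_set_enumeration(self, random_images, connectivity):
        for img in random_images(12, shape=(12, 12), levels=8, seed=5):
            tree = build_max_tree(img, connectivity=connectivity)
            assert tree_node_set(tree) == upper_level_components(img, connectivity)

    def test_reconstruction_identity(self, random_images):
        for img in random_images(10, shape=(14, 14), levels=16, seed=7):
            tree = build_max_tree(img)
            np.testing.assert_array_equal(tree.reconstruct(), img)

    def test_leaves_are_regional_maxima(self, random_images):
        from oracles import regional_maxima

        for img in random_images(6, shape=(12, 12), levels=6, seed=11):
            tree = build_max_tree(img)
            reps = set()
            for leaf in tree.leaves():
                reps.add(int(tree.proper_pixels(leaf).min()))
            assert reps == {rep for _, rep, _ in regional_maxima(img)}

    def test_monotone_levels_and_areas_along_branches(self, random_images):
        for img in random_images(6, shape=(12, 12), levels=8, seed=13):
            tree = build_max_tree(img)
            for i in range(1, tree.n_nodes):
                p = tree.parent[i]
                assert tree.level[p] < tree.level[i]
                assert tree.area[p] >= tree.area[i]


class TestMinTree:
    def test_duality_with_inverted_max_tree(self, random_images):
        for img in random_images(5, shape=(10, 10), levels=8, seed=17):
            min_tree = build_min_tree(img)
            max_tree = build_max_tree(255 - img)
            assert tree_node_set(min_tree) == tree_node_set(max_tree)

    def test_constant_image(self):
        tree = build_min_tree(np.full((4, 4), 9, dtype=np.uint8))
        assert tree.n_nodes == 1
        assert tree.original_level[0] == 9

    def test_dark_pit_is_a_leaf(self):
        img = np.full((7, 7), 200, dtype=np.uint8)
        img[3, 3] = 20
        tree = build_min_tree(img)
        leaves = tree.leaves()
        assert len(leaves) == 1
        rows, cols = node_pixel_set(tree, leaves[0])
        assert (rows.tolist(), cols.tolist()) == ([3], [3])
        assert tree.original_level[leaves[0]] == 20


class TestAttributes:
    def test_root_area_is_total_pixels(self, rng):
        img = rng.integers(0, 8, size=(9, 11)).astype(np.uint8)
        tree = build_max_tree(img)
        attrs = compute_attributes(tree)
        assert attrs.area[tree.root] == img.size

    def test_two_by_two_block_moments(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[1:3, 1:3] = 10
        tree = build_max_tree(img)
        attrs = compute_attributes(tree)
        node = int(np.flatnonzero(tree.level == 10)[0])
        mu20, mu02, mu11 = (m[node] for m in attrs.central_moments())
        assert mu20 == pytest.approx(1.0)
        assert mu02 == pytest.approx(1.0)
        assert mu11 == pytest.approx(0.0)

    def test_incremental_equals_direct(self, random_images):
        """Propagated sums must match direct summation over explicit pixels."""
        for img in random_images(8, shape=(12, 12), levels=8, seed=23):
            tree = build_max_tree(img)
            attrs = compute_attributes(tree, with_hull=True)
            for node in range(tree.n_nodes):
                rows, cols = node_pixel_set(tree, node)
                x, y = cols.astype(float), rows.astype(float)
                vals = img[rows, cols]
                assert attrs.area[node] == rows.size
                assert attrs.sum_x[node] == pytest.approx(x.sum())
                assert attrs.sum_xx[node] == pytest.approx((x * x).sum())
                assert attrs.sum_xy[node] == pytest.approx((x * y).sum())
                assert attrs.f_min[node] == vals.min()
                assert attrs.f_max[node] == vals.max()
                assert attrs.hull_area(node) == pytest.approx(
                    hull_area_shapely(rows, cols), abs=1e-9
                )

    def test_area_decomposition(self, random_images):
        """A(node) = sum of children areas + proper pixels."""
        for img in random_images(4, shape=(10, 10), levels=6, seed=29):
            tree = build_max_tree(img)
            kids = tree.children_lists()
            for node in range(tree.n_nodes):
                total = sum(tree.area[c] for c in kids[node])
                assert tree.area[node] == total + tree.proper_pixels(node).size

    def test_shape_mismatch_rejected(self):
        tree = build_max_tree(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            compute_attributes(tree, np.zeros((5, 5), dtype=np.uint8))


class TestNodePixelSet:
    def test_root_covers_image(self, rng):
        img = rng.integers(0, 4, size=(6, 6)).astype(np.uint8)
        tree = build_max_tree(img)
        rows, _ = node_pixel_set(tree, tree.root)
        assert rows.size == img.size

    def test_sibling_sets_disjoint(self):
        img = np.zeros((6, 6), dtype=np.uint8)
        img[1:3, 1:3] = 100
        img[3, 4] = 200
        tree = build_max_tree(img)
        sets = []
        for node in range(1, tree.n_nodes):
            rows, cols = node_pixel_set(tree, node)
            sets.append(set(zip(rows.tolist(), cols.tolist())))
        assert not (sets[0] & sets[1])

    def test_invalid_node_rejected(self):
        tree = build_max_tree(np.zeros((3, 3), dtype=np.uint8))
        with pytest.raises(IndexError):
            node_pixel_set(tree, 99)


class TestAreaOpening:
    def test_fig_style_toy_scene(self):
        from agrimorph.synth import generate_toy_binary

        img = generate_toy_binary().astype(np.uint8) * 255
        opened = area_opening(img, 9)
        from scipy import ndimage

        before = ndimage.label(img > 0)[1]
        after = ndimage.label(opened > 0)[1]
        assert (before, after) == (3, 2)
        # The thin elongated object survives untouched.
        assert np.array_equal((opened > 0)[11, 4:16], np.ones(12, dtype=bool))

    def test_identity_when_threshold_one(self, rng):
        img = rng.integers(0, 16, size=(10, 10)).astype(np.uint8)
        np.testing.assert_array_equal(area_opening(img, 1), img)

    def test_flattens_to_minimum_when_threshold_huge(self, rng):
        img = rng.integers(3, 16, size=(8, 8)).astype(np.uint8)
        out = area_opening(img, img.size + 1)
        assert (out == img.min()).all()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            area_opening(np.zeros((3, 3), dtype=np.uint8), 0)

    def test_matches_stacked_binary_opening_and_skimage(self, random_images):
        for img in random_images(8, shape=(12, 12), levels=8, seed=31):
            for t in (2, 5, 9, 20):
                ours = area_opening(img, t)
                np.testing.assert_array_equal(ours, stacked_area_opening(img, t))
                np.testing.assert_array_equal(
                    ours, skimage_area_opening(img, area_threshold=t, connectivity=1)
                )

    def test_anti_extensive_and_idempotent(self, random_images):
        for img in random_images(4, shape=(10, 10), levels=10, seed=37):
            out = area_opening(img, 6)
            assert (out <= img).all()
            np.testing.assert_array_equal(area_opening(out, 6), out)
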