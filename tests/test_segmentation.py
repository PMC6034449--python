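import dataclasses

import numpy as np
import pytest

from agrimorph.evaluation import pixel_metrics
from agrimorph.maxtree import build_max_tree
from agrimorph.segmentation import (
    MaxTreeSegmenter,
    RegionCandidate,
    SegmentationParams,
    branch_of,
    growth_factor,
    growth_factors,
    result_to_mask,
    segment,
    select_region_on_branch,
)
from agrimorph.synth import FieldSpec, generate_field
from oracles import component_area_at


def disk_image(shape=(128, 128), center=(64, 64), radius=20,
               background=40, level=160):
    img = np.full(shape, background, dtype=np.uint8)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    disk = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    img[disk] = level
    return img, disk


class TestBranch:
    def test_ramp_threshold_decomposition(self):
        img = np.array([[0, 1, 2, 3]], dtype=np.uint8)
        tree = build_max_tree(img)
        branch = branch_of(tree, int(tree.leaves()[0]))
        assert [(c.level, c.area) for c in branch] == [(3, 1), (2, 2), (1, 3), (0, 4)]

    def test_single_node_tree(self):
        tree = build_max_tree(np.full((3, 3), 5, dtype=np.uint8))
        assert len(branch_of(tree, 0)) == 1

    def test_non_leaf_rejected(self):
        img, _ = disk_image()
        tree = build_max_tree(img)
        with pytest.raises(ValueError, match="leaf"):
            branch_of(tree, int(tree.root))

    def test_areas_sorted_along_random_branches(self, random_images):
        for img in random_images(5, shape=(12, 12), levels=8, seed=59):
            tree = build_max_tree(img)
            for leaf in tree.leaves():
                areas = [c.area for c in branch_of(tree, int(leaf))]
                assert areas == sorted(areas)

    def test_branch_areas_match_thresholding(self, random_images):
        """Each candidate's area equals the component of {f >= level}."""
        for img in random_images(4, shape=(10, 10), levels=6, seed=61):
            tree = build_max_tree(img)
            for leaf in tree.leaves()[:3]:
                pixel = np.unravel_index(tree.proper_pixels(int(leaf))[0], img.shape)
                for cand in branch_of(tree, int(leaf)):
                    assert cand.area == component_area_at(img, pixel, cand.level)


class TestGrowthFactor:
    def test_arithmetic(self):
        branch = [
            RegionCandidate(node=1, level=100, area=100),
            RegionCandidate(node=0, level=70, area=300),
        ]
        assert growth_factor(branch, 0, 30) == pytest.approx(2.0)

    def test_stable_region_has_zero_growth(self):
        branch = [
            RegionCandidate(node=2, level=50, area=10),
            RegionCandidate(node=1, level=20, area=10),
            RegionCandidate(node=0, level=0, area=10),
        ]
        assert growth_factor(branch, 0, 30) == pytest.approx(0.0)

    def test_ramp_enumerated_level_sets(self):
        img = np.arange(9, -1, -1, dtype=np.uint8).reshape(1, 10)
        tree = build_max_tree(img)
        branch = growth_factors(branch_of(tree, int(tree.leaves()[0])), 3)
        # Leaf at level 9 (area 1) vs component at level 6 (area 4).
        assert branch[0].growth == pytest.approx(3.0)

    def test_root_area_used_when_branch_ends(self):
        branch = [
            RegionCandidate(node=1, level=10, area=5),
            RegionCandidate(node=0, level=8, area=50),
        ]
        # 10 - 30 < root level: fall back to the root's area.
        assert growth_factor(branch, 0, 30) == pytest.approx(9.0)


def make_branch(specs):
    """Branch from (level, area) pairs with externally assigned growths."""
    return [
        RegionCandidate(node=i, level=lvl, area=area, growth=g)
        for i, (lvl, area, g) in enumerate(specs)
    ]


class TestSelectRegionOnBranch:
    def test_flat_branch_yields_none(self):
        branch = make_branch([(50, 10, 0.0), (20, 10, 0.0), (0, 10, 0.0)])
        assert select_region_on_branch(branch, SegmentationParams()) is None

    def test_no_large_competitor_keeps_argmax(self):
        branch = make_branch([(90, 10, 50.0), (60, 40, 20.0), (0, 1000, 12.0)])
        chosen = select_region_on_branch(branch, SegmentationParams())
        assert chosen.node == 0 and chosen.growth == 50.0

    def test_adjustment_adopts_confirmed_larger_region(self):
        # B0: G=50, A=10.  R: G=20, A=200 > 15*10, followed by six
        # consecutive candidates with areas within +-15% and G > 10.
        specs = [(120, 10, 50.0), (100, 200, 20.0)]
        specs += [(95 - i, 204 + 4 * i, 19.0 - i) for i in range(6)]
        chosen = select_region_on_branch(make_branch(specs),
                                         SegmentationParams())
        assert chosen.node == 1
        assert chosen.area == 200

    def test_adjustment_requires_full_run(self):
        # Only 4 similar followers: below l_run=6, so B stays the argmax.
        specs = [(120, 10, 50.0), (100, 200, 20.0)]
        specs += [(95 - i, 205 + 5 * i, 19.0 - i) for i in range(4)]
        specs += [(80, 5000, 11.0)]
        chosen = select_region_on_branch(make_branch(specs),
                                         SegmentationParams())
        assert chosen.node == 0

    def test_growth_at_most_gmin_yields_none(self):
        branch = make_branch([(50, 10, 10.0), (0, 100, 3.0)])
        assert select_region_on_branch(branch, SegmentationParams()) is None


class TestSegment:
    def test_constant_image_empty_result(self):
        result = segment(np.full((32, 32), 25, dtype=np.uint8))
        assert len(result) == 0
        assert not result.to_mask().values.any()

    def test_single_disk_recovered_exactly(self):
        img, disk = disk_image()
        result = segment(img)
        assert len(result) == 1
        np.testing.assert_array_equal(result.to_mask().values, disk)

    def test_two_peaks_in_one_blob_deduplicated(self):
        # Two broad plateaus whose own growth stays below g_min inside one
        # strongly contrasted blob: both marker branches converge on the
        # blob node, which is accepted exactly once.
        img, disk = disk_image(background=40, level=142)
        img[50:62, 50:62] = 172
        img[66:78, 66:78] = 172
        result = segment(img)
        assert len(result.tree.leaves()) >= 2
        assert result.n_markers == 2
        assert len(result) == 1
        np.testing.assert_array_equal(result.to_mask().values, disk)

    def test_grey_shift_invariance(self):
        sample = generate_field(FieldSpec(seed=2, n_plants=4))
        img = sample.ndvi.values
        masks = []
        for shift in (0, 30):
            result = segment((img.astype(np.int64) + shift).astype(np.uint8))
            masks.append(result.to_mask().values)
        np.testing.assert_array_equal(masks[0], masks[1])

    def test_locality_distant_blob_does_not_disturb(self):
        img, disk = disk_image(shape=(160, 160), center=(50, 50))
        base = segment(img)
        img2 = img.copy()
        yy, xx = np.mgrid[:160, :160]
        far = (yy - 130) ** 2 + (xx - 130) ** 2 <= 10**2
        img2[far] = 200
        augmented = segment(img2)
        base_sets = {frozenset(zip(*base.pixel_set(i))) for i in range(len(base))}
        aug_sets = {
            frozenset(zip(*augmented.pixel_set(i))) for i in range(len(augmented))
        }
        assert base_sets <= aug_sets

    def test_determinism(self):
        sample = generate_field(FieldSpec(seed=4, n_plants=5))
        a = segment(sample.ndvi.values)
        b = segment(sample.ndvi.values)
        assert [dataclasses.astuple(r) for r in a.regions] == [
            dataclasses.astuple(r) for r in b.regions
        ]

    def test_area_threshold_filters_small_regions(self):
        img, disk = disk_image(radius=5)  # 81 px
        assert len(segment(img, SegmentationParams(area_threshold=200))) == 0
        assert len(segment(img, SegmentationParams(area_threshold=50))) == 1

    def test_recovery_on_synthetic_field(self):
        sample = generate_field(FieldSpec(seed=9, n_plants=6))
        result = segment(sample.ndvi.values,
                         SegmentationParams(area_threshold=50))
        metrics = pixel_metrics(result.to_mask(), sample.truth)
        assert metrics.f1 >= 0.9


class TestResultOutputs:
    def test_mask_is_union_and_nested_regions_union_to_outermost(self):
        img, disk = disk_image()
        img[60:68, 60:68] = 200  # nested brighter square
        result = segment(img)
        mask = result_to_mask(result).values
        union = np.zeros_like(mask)
        for i in range(len(result)):
            rows, cols = result.pixel_set(i)
            union[rows, cols] = True
        np.testing.assert_array_equal(mask, union)

    def test_shape_mismatch_rejected(self):
        img, _ = disk_image()
        result = segment(img)
        with pytest.raises(ValueError):
            result_to_mask(result, shape=(4, 4))

    def test_label_image_nested_overwrite(self):
        img, disk = disk_image()
        img[60:68, 60:68] = 200
        result = segment(img)
        labels = result.to_label_image()
        assert labels.dtype == np.uint16
        assert len(np.unique(labels)) == len(result) + 1
        if len(result) == 2:
            inner = min(result.regions, key=lambda r: r.area)
            assert (labels[62, 62] != labels[50, 64])

    def test_dataframe_export_columns(self):
        img, _ = disk_image()
        frame = segment(img).to_dataframe()
        assert list(frame.columns) == [
            "region", "node", "marker_row", "marker_col",
            "level", "area", "growth",
        ]


class TestSegmenterEstimator:
    def test_get_set_params_roundtrip(self):
        seg = MaxTreeSegmenter(delta=25).set_params(area_threshold=50)
        params = seg.get_params()
        assert params["delta"] == 25 and params["area_threshold"] == 50
        with pytest.raises(ValueError):
            seg.set_params(bogus=1)

    def test_predict_returns_mask(self):
        img, disk = disk_image()
        mask = MaxTreeSegmenter().fit().predict(img)
        np.testing.assert_array_equal(mask, disk)
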