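"""Crop extraction, local segmentation, reseeding and the full grow loop."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import YBRANCH_SEED, dice
from smrg.growing import (GrowConfig, ImageStack, Seed, detect_somata,
                          extract_crop, grow, next_seeds, segment_crop)
from smrg.phantom import Branch, PhantomSpec, rasterize, render, standard_suite

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class TestExtractCrop:
    def test_large_stack_uses_one_eighth_of_plane(self):
        stack = ImageStack(np.zeros((143, 512, 512), dtype=np.uint8))
        crop, _ = extract_crop(stack, Seed(70, 250, 250))
        assert crop.shape == (3, 64, 64)

    def test_small_stack_raises_to_floor(self):
        stack = ImageStack(np.zeros((50, 128, 128), dtype=np.uint8))
        crop, _ = extract_crop(stack, Seed(25, 60, 60))
        assert crop.shape == (3, 32, 32)

    def test_corner_seed_offset_consistency(self):
        rng = np.random.default_rng(0)
        stack = ImageStack(rng.integers(0, 255, (20, 64, 64)))
        crop, offset = extract_crop(stack, Seed(0, 0, 0))
        assert crop.shape == (3, 32, 32)
        for c in [(0, 0, 0), (2, 31, 31), (1, 7, 19)]:
            assert crop[c] == stack.voxels[tuple(np.add(c, offset))]

    def test_out_of_bounds_seed_rejected(self):
        stack = ImageStack(np.zeros((10, 64, 64), dtype=np.uint8))
        with pytest.raises(ValueError):
            extract_crop(stack, Seed(10, 0, 0))


class TestSegmentCrop:
    def test_pure_background_admits_nothing(self):
        rng = np.random.default_rng(1)
        crop = np.clip(100 + np.round(rng.normal(0, 5, (3, 32, 32))), 0, None
                       ).astype(np.int64)
        local = segment_crop(crop, Seed(1, 16, 16))
        assert local.sum() <= 1

    def test_bright_tube_recovered(self):
        spec = PhantomSpec([Branch((1, 16, 2), (1, 16, 30), 4.0, 4.0)], None,
                           (3, 32, 32))
        truth = rasterize(spec)
        stack = render(truth, rng_seed=5)
        local = segment_crop(stack.voxels, Seed(1, 16, 16))
        assert dice(local, truth.mask) >= 0.9

    def test_only_seed_connected_blob_admitted(self):
        crop = np.full((3, 32, 32), 100, dtype=np.int64)
        crop[1, 4:10, 4:10] = 250
        crop[1, 20:26, 20:26] = 250
        local = segment_crop(crop, Seed(1, 6, 6))
        assert local[1, 4:10, 4:10].all()
        assert not local[1, 20:26, 20:26].any()

    def test_seed_failing_rule_gives_empty_mask(self):
        crop = np.full((3, 32, 32), 100, dtype=np.int64)
        crop[1, 4:10, 4:10] = 250
        local = segment_crop(crop, Seed(1, 25, 25))
        assert not local.any()


class TestNextSeeds:
    def test_disk_yields_center(self):
        mask = np.zeros((1, 33, 33), dtype=bool)
        yy, xx = np.ogrid[:33, :33]
        mask[0] = (yy - 16) ** 2 + (xx - 16) ** 2 <= 100
        seeds = next_seeds(mask)
        assert seeds == [Seed(0, 16, 16)]

    def test_two_disks_yield_two_seeds(self):
        mask = np.zeros((1, 33, 66), dtype=bool)
        yy, xx = np.ogrid[:33, :66]
        mask[0] = ((yy - 16) ** 2 + (xx - 12) ** 2 <= 64) \
            | ((yy - 16) ** 2 + (xx - 50) ** 2 <= 64)
        seeds = next_seeds(mask)
        assert len(seeds) >= 2
        assert Seed(0, 16, 12) in seeds and Seed(0, 16, 50) in seeds

    def test_tube_seeds_lie_on_axis(self):
        spec = PhantomSpec([Branch((1, 16, 2), (1, 16, 62), 3.0, 3.0)], None,
                           (3, 32, 64))
        truth = rasterize(spec)
        for s in next_seeds(truth.mask):
            if s.z == 1:  # central plane carries the axis
                assert abs(s.y - 16) <= 1

    def test_offset_mapping_and_empty_mask(self):
        assert next_seeds(np.zeros((2, 5, 5), dtype=bool)) == []
        mask = np.zeros((1, 9, 9), dtype=bool)
        mask[0, 4, 4] = True
        assert next_seeds(mask, offset=(7, 10, 20)) == [Seed(7, 14, 24)]


class TestGrow:
    def test_uniform_background_terminates_empty(self):
        stack = ImageStack(np.full((8, 64, 64), 100, dtype=np.int64))
        seg = grow(stack, [Seed(4, 32, 32)])
        assert seg.n_voxels <= 1
        assert len(seg.seed_history) == 1

    def test_ybranch_dice_and_branch_coverage(self, ybranch_high,
                                              ybranch_segmentation):
        """Reseeding must carry the growth across many crops into both
        branch tips, with high overlap against the rasterised truth."""
        _, truth = ybranch_high
        seg = ybranch_segmentation
        assert dice(seg.mask, truth.mask) >= 0.90
        assert len(seg.seed_history) > 10            # beyond one crop
        for tip in [(6, 24, 36), (10, 24, 92)]:      # branch end points
            region = seg.mask[tip[0] - 3:tip[0] + 4, tip[1]:tip[1] + 7,
                              tip[2] - 3:tip[2] + 4]
            assert region.any()

    def test_mask_is_26_connected_to_seed(self, ybranch_segmentation):
        labels, n = ndimage.label(ybranch_segmentation.mask, structure=_STRUCT26)
        assert n == 1
        assert labels[YBRANCH_SEED] == 1

    def test_deterministic(self, ybranch_high, ybranch_segmentation):
        stack, _ = ybranch_high
        again = grow(stack, [YBRANCH_SEED])
        assert np.array_equal(again.mask, ybranch_segmentation.mask)
        assert again.seed_history == ybranch_segmentation.seed_history

    def test_no_seed_raises(self, ybranch_high):
        with pytest.raises(ValueError):
            grow(ybranch_high[0], [])

    def test_low_contrast_degrades_without_crash(self):
        stack, _ = standard_suite("ybranch", "low")
        seg = grow(stack, [YBRANCH_SEED])
        if seg.n_voxels:
            labels, n = ndimage.label(seg.mask, structure=_STRUCT26)
            assert n == 1


class TestDetectSomata:
    def test_single_sphere_found_at_center(self):
        spec = PhantomSpec([], ((8, 40, 40), 8.0), (16, 80, 80))
        stack = render(rasterize(spec), rng_seed=3)
        seeds = detect_somata(stack, (6, 10))
        assert len(seeds) == 1
        assert np.linalg.norm(np.subtract(seeds[0], (8, 40, 40))) <= 2

    def test_empty_stack_yields_nothing(self):
        stack = ImageStack(np.full((16, 64, 64), 100, dtype=np.int64))
        assert detect_somata(stack, (6, 10)) == []

    def test_two_separated_spheres_found(self):
        stack, truth = standard_suite("somata", "high")
        seeds = detect_somata(stack, (6, 10))
        assert len(seeds) == 2
        got = sorted(tuple(s) for s in seeds)
        for found, want in zip(got, [(8, 64, 54), (8, 64, 70)]):
            assert np.linalg.norm(np.subtract(found, want)) <= 2

    def test_invalid_radius_range(self):
        stack = ImageStack(np.zeros((8, 64, 64), dtype=np.uint8))
        with pytest.raises(ValueError):
            detect_somata(stack, (0, 5))


class TestGrowConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GrowConfig(crop_min=16)
        with pytest.raises(ValueError):
            GrowConfig(crop_depth=4)
        with pytest.raises(ValueError):
            GrowConfig(posterior_threshold=1.0)
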