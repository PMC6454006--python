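"""Patch-dataset construction: crop geometry, centering, SN duplication,
border targets and augmentation invariants."""

import numpy as np
import pytest

from histotools import seg_data
from histotools.io import TileRecord
from histotools.seg_data import AugmentParams, SegPatch


def _tile(side=308, seed=0, with_mask=True):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(side, side, 3), dtype=np.uint8)
    mask = np.zeros((side, side), dtype=np.int32) if with_mask else None
    return TileRecord(img, mask, id="t")


class TestExtractNbl:
    def test_exact_fit_tile_gives_one_sliding_position(self):
        tile = _tile(200)
        patches = seg_data.extract_nbl(tile, n_random=30,
                                       rng=np.random.default_rng(0))
        assert len(patches) == 1 + 30

    def test_window_count_308(self):
        # floor((308-200)/54)+1 = 3 positions per axis
        tile = _tile(308)
        patches = seg_data.extract_nbl(tile, n_random=30,
                                       rng=np.random.default_rng(0))
        assert len(patches) == 9 + 30
        sliding = {p.offset for p in patches[:9]}
        assert sliding == {(r, c) for r in (0, 54, 108) for c in (0, 54, 108)}

    def test_patch_shape_and_determinism(self):
        tile = _tile(250)
        a = seg_data.extract_nbl(tile, n_random=5, rng=np.random.default_rng(3))
        b = seg_data.extract_nbl(tile, n_random=5, rng=np.random.default_rng(3))
        assert all(p.image.shape == (200, 200, 3) for p in a)
        assert [p.offset for p in a] == [p.offset for p in b]

    def test_small_tile_rejected(self):
        with pytest.raises(ValueError):
            seg_data.extract_nbl(_tile(150), rng=np.random.default_rng(0))


class TestExtractNbd:
    def _tile_with_nuclei(self, centers, side=400):
        img = np.zeros((side, side, 3), dtype=np.uint8)
        mask = np.zeros((side, side), dtype=np.int32)
        for i, (r, c) in enumerate(centers, start=1):
            mask[r - 3:r + 4, c - 3:c + 4] = i  # 7x7 square, centroid (r, c)
        return TileRecord(img, mask, id="n")

    def test_single_center_nucleus_is_centered(self):
        tile = self._tile_with_nuclei([(200, 200)])
        patches = seg_data.extract_nbd(tile)
        assert len(patches) == 1
        assert patches[0].offset == (100, 100)
        # centroid lands on the patch center (100, 100)
        blob = patches[0].blob_target
        rr, cc = np.nonzero(blob)
        assert (round(rr.mean()), round(cc.mean())) == (100, 100)

    def test_edge_nuclei_ignored(self):
        interior = [(150, 150), (200, 200), (250, 250), (150, 250), (250, 150)]
        edge = [(50, 200), (200, 370)]
        tile = self._tile_with_nuclei(interior + edge)
        patches = seg_data.extract_nbd(tile)
        assert len(patches) == 5

    def test_empty_mask_gives_empty_list(self):
        tile = _tile(300)
        assert seg_data.extract_nbd(tile) == []

    def test_missing_mask_rejected(self):
        with pytest.raises(ValueError):
            seg_data.extract_nbd(_tile(300, with_mask=False))


class TestExtractSn:
    def _nbl_patch(self, center_fraction):
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        blob = np.zeros((200, 200), dtype=np.uint8)
        n_px = int(round(center_fraction * 54 * 54))
        flat = np.zeros(54 * 54, dtype=np.uint8)
        flat[:n_px] = 1
        blob[73:127, 73:127] = flat.reshape(54, 54)
        return SegPatch(img, blob, np.zeros_like(blob), "NBL")

    @pytest.mark.parametrize("fraction,expected_copies", [
        (0.30, 3), (0.50, 3), (0.60, 0),
    ])
    def test_center_fraction_rule_inclusive(self, fraction, expected_copies):
        out = seg_data.extract_sn([self._nbl_patch(fraction)])
        assert len(out) == expected_copies
        assert all(p.tag == "SN" for p in out)

    def test_sn_images_equal_source_bytes(self):
        patch = self._nbl_patch(0.2)
        out = seg_data.extract_sn([patch])
        for p in out:
            assert np.array_equal(p.image, patch.image)

    def test_non_nbl_rejected(self):
        patch = self._nbl_patch(0.2)
        patch.tag = "NBD"
        with pytest.raises(ValueError):
            seg_data.extract_sn([patch])


class TestBorderTarget:
    def test_square_outline_thickened(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5:15, 5:15] = 1
        assert seg_data.make_border_target(mask, thickness=1).sum() == 36
        assert seg_data.make_border_target(mask, thickness=2).sum() == 64

    def test_empty_mask(self):
        assert not seg_data.make_border_target(np.zeros((10, 10), int)).any()

    def test_touching_objects_share_interface(self):
        mask = np.zeros((10, 12), dtype=np.int32)
        mask[2:8, 2:6] = 1
        mask[2:8, 6:10] = 2
        border = seg_data.make_border_target(mask, thickness=1)
        # columns 5 and 6 are the interface and must be border on both sides
        assert border[4, 5] == 1 and border[4, 6] == 1

    def test_border_subset_of_dilated_outline(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((30, 30), dtype=np.int32)
        mask[3:12, 4:14] = 1
        mask[15:26, 10:22] = 2
        outline = seg_data.make_border_target(mask, thickness=1).astype(bool)
        thick = seg_data.make_border_target(mask, thickness=2).astype(bool)
        from scipy import ndimage as ndi
        dilated = ndi.binary_dilation(outline, np.ones((3, 3), bool))
        assert (thick <= dilated).all()
        assert (outline <= thick).all()


class TestAugment:
    def _patch(self, seed=0):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(200, 200, 3), dtype=np.uint8)
        blob = (rng.random((200, 200)) < 0.3).astype(np.uint8)
        border = (rng.random((200, 200)) < 0.1).astype(np.uint8)
        return SegPatch(img, blob, border, "NBL")

    def test_identity_draw_is_noop(self):
        patch = self._patch()
        identity = AugmentParams(shift_range=(0, 0), rotation_range=(0, 0),
                                 flip_probability=0.0, shear_range=(0, 0),
                                 resize_range=(1, 1))
        out = seg_data.augment(patch, identity, np.random.default_rng(0))
        assert np.array_equal(out.image, patch.image)
        assert np.array_equal(out.blob_target, patch.blob_target)

    def test_certain_flip_reverses_columns(self):
        patch = self._patch()
        flip = AugmentParams(shift_range=(0, 0), rotation_range=(0, 0),
                             flip_probability=1.0, shear_range=(0, 0),
                             resize_range=(1, 1))
        out = seg_data.augment(patch, flip, np.random.default_rng(0))
        # flipping both axes = 180 degree rotation of the grid
        assert np.array_equal(out.blob_target, patch.blob_target[::-1, ::-1])

    def test_targets_stay_binary_under_random_draws(self):
        patch = self._patch()
        rng = np.random.default_rng(5)
        for _ in range(5):
            out = seg_data.augment(patch, AugmentParams(), rng)
            assert set(np.unique(out.blob_target)) <= {0, 1}
            assert set(np.unique(out.border_target)) <= {0, 1}
            assert out.image.shape == (200, 200, 3)

    def test_default_ranges(self):
        p = AugmentParams()
        assert p.shift_range == (-0.05, 0.05)
        assert p.rotation_range == (-45.0, 45.0)
        assert p.shear_range == (-0.4 * np.pi, 0.4 * np.pi)
        assert p.resize_range == (0.6, 2.0)
        assert p.repeats == 3


class TestCrops:
    def test_center_crop_offset(self):
        arr = np.arange(200 * 200).reshape(200, 200)
        crop = seg_data.center_crop(arr, 102)
        assert crop.shape == (102, 102)
        assert crop[0, 0] == arr[49, 49]

    def test_target_crop_aligns_with_input_center(self):
        arr = np.arange(200 * 200).reshape(200, 200)
        inner = seg_data.center_crop(arr, 102)
        target = seg_data.target_crop(arr, 54)
        # the 54 window sits at the center of the 102 window
        assert np.array_equal(seg_data.center_crop(inner, 54), target)

    def test_crop_of_crop_composes(self):
        arr = np.arange(200 * 200).reshape(200, 200)
        once = seg_data.center_crop(seg_data.center_crop(arr, 150), 100)
        direct = seg_data.center_crop(arr, 100)
        assert np.array_equal(once, direct)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            seg_data.center_crop(np.zeros((50, 50)), 102)
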