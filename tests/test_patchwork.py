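import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalseg.patchwork import (
    PatchSpec,
    RoiBox,
    STAGE1_SPEC,
    STAGE2_SPEC,
    center_crop_xy,
    clip_z_cubes,
    crop_roi,
    find_kidney_rois,
    restore_roi,
    stitch_cubes,
    uncrop_xy,
    z_cube_offsets,
)


def brute_force_offsets(n, cube_len, stride):
    """Independent enumeration oracle: regular grid + end alignment."""
    if n <= cube_len:
        return [0]
    offs = [s for s in range(0, n - cube_len + 1, stride)]
    covered = max(offs) + cube_len
    if covered < n:
        offs.append(n - cube_len)
    return offs


class TestPatchSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            PatchSpec(crop_xy=(64, 64), cube_len=32, stride=0)
        with pytest.raises(ValueError):
            PatchSpec(crop_xy=(64, 64), cube_len=32, stride=40)
        with pytest.raises(ValueError):
            PatchSpec(crop_xy=(0, 64), cube_len=32, stride=16)

    def test_paper_specs(self):
        assert (STAGE1_SPEC.cube_len, STAGE1_SPEC.stride) == (96, 48)
        assert STAGE1_SPEC.crop_xy == (192, 192)
        assert (STAGE2_SPEC.cube_len, STAGE2_SPEC.stride) == (64, 32)
        assert STAGE2_SPEC.crop_xy == (160, 160)


class TestCenterCrop:
    def test_offsets_256_to_192(self):
        arr = np.zeros((2, 256, 256))
        out, off = center_crop_xy(arr, (192, 192))
        assert out.shape == (2, 192, 192)
        assert off == (32, 32)

    def test_identity(self, rng):
        arr = rng.normal(size=(3, 64, 64))
        out, off = center_crop_xy(arr, (64, 64))
        np.testing.assert_array_equal(out, arr)
        assert off == (0, 0)

    def test_pad_small_input_roundtrip(self, rng):
        arr = rng.normal(size=(2, 160, 160)).astype(np.float32)
        out, off = center_crop_xy(arr, (192, 192))
        assert out.shape == (2, 192, 192)
        assert off == (-16, -16)
        back = uncrop_xy(out, off, (160, 160))
        np.testing.assert_array_equal(back, arr)

    def test_crop_content_matches_slice(self, rng):
        arr = rng.normal(size=(1, 100, 80))
        out, (oy, ox) = center_crop_xy(arr, (40, 40))
        np.testing.assert_array_equal(out, arr[:, oy : oy + 40, ox : ox + 40])


class TestZCubeOffsets:
    def test_exact_fit(self):
        assert z_cube_offsets(96, 96, 48) == [0]

    def test_two_regular(self):
        assert z_cube_offsets(144, 96, 48) == [0, 48]

    def test_end_aligned(self):
        assert z_cube_offsets(100, 96, 48) == [0, 4]

    def test_short_volume(self):
        assert z_cube_offsets(50, 96, 48) == [0]

    @given(n=st.integers(1, 300))
    @settings(max_examples=60, deadline=None)
    def test_matches_oracle_and_covers(self, n):
        for cube_len, stride in ((96, 48), (64, 32), (32, 16)):
            offs = z_cube_offsets(n, cube_len, stride)
            assert offs == brute_force_offsets(n, cube_len, stride)
            covered = set()
            for o in offs:
                covered |= set(range(o, min(o + cube_len, n)))
            assert covered == set(range(n))


class TestClipStitch:
    def test_roundtrip_identity_scorer(self, rng):
        arr = rng.normal(size=(100, 8, 8)).astype(np.float32)
        spec = PatchSpec(crop_xy=(8, 8), cube_len=96, stride=48)
        grid = clip_z_cubes(arr, spec)
        back = stitch_cubes(grid)
        np.testing.assert_allclose(back, arr, atol=1e-6)

    def test_overlap_mean_rule(self):
        spec = PatchSpec(crop_xy=(4, 4), cube_len=8, stride=4)
        arr = np.zeros((12, 4, 4), dtype=np.float32)
        grid = clip_z_cubes(arr, spec)
        assert grid.offsets == [0, 4]
        scores = [np.full((1, 8, 4, 4), 2.0, dtype=np.float32),
                  np.full((1, 8, 4, 4), 4.0, dtype=np.float32)]
        out = stitch_cubes(grid, scores)
        np.testing.assert_array_equal(out[0, :4], 2.0)
        np.testing.assert_array_equal(out[0, 4:8], 3.0)  # (2 + 4) / 2
        np.testing.assert_array_equal(out[0, 8:], 4.0)

    def test_against_bruteforce_averaging_oracle(self, rng):
        spec = PatchSpec(crop_xy=(5, 5), cube_len=6, stride=3)
        arr = rng.normal(size=(14, 5, 5)).astype(np.float32)
        grid = clip_z_cubes(arr, spec)
        scores = [rng.normal(size=(2, 6, 5, 5)).astype(np.float32) for _ in grid.cubes]
        out = stitch_cubes(grid, scores)
        # oracle: per-voxel loop over all covering cubes
        expected = np.zeros((2, 14, 5, 5))
        for z in range(14):
            vals = []
            for cube, off in zip(scores, grid.offsets):
                if off <= z < off + 6:
                    vals.append(cube[:, z - off])
            expected[:, z] = np.mean(vals, axis=0)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_short_volume_padding_dropped(self, rng):
        arr = rng.normal(size=(10, 4, 4)).astype(np.float32)
        spec = PatchSpec(crop_xy=(4, 4), cube_len=16, stride=8)
        grid = clip_z_cubes(arr, spec)
        assert len(grid) == 1 and grid.cubes[0].shape == (16, 4, 4)
        back = stitch_cubes(grid)
        assert back.shape == (10, 4, 4)
        np.testing.assert_allclose(back, arr)


class TestFindKidneyRois:
    def test_phantom_two_rois_contain_centroids(self, tiny_phantom):
        _, lab, truth = tiny_phantom
        boxes = find_kidney_rois(
            (lab.voxels > 0).astype(np.int16), lab.spacing, crop_yx=(32, 32),
            min_volume_mm3=500.0,
        )
        assert len(boxes) == 2
        for kid in truth.kidneys:
            cz, cy, cx = kid.centroid_voxel
            hits = [
                b for b in boxes
                if b.z0 <= cz < b.z1
                and b.y0 <= cy < b.y0 + 32
                and b.x0 <= cx < b.x0 + 32
            ]
            assert len(hits) == 1

    def test_speck_below_threshold_discarded(self):
        mask = np.zeros((20, 40, 40), dtype=np.int16)
        mask[5:15, 5:20, 5:20] = 1  # 2250 voxels
        mask[18, 35, 35] = 1  # 3-voxel speck
        mask[18, 35, 36] = 1
        mask[18, 36, 35] = 1
        boxes = find_kidney_rois(mask, (1.0, 1.0, 1.0), crop_yx=(16, 16), min_volume_mm3=100.0)
        assert len(boxes) == 1

    def test_empty_mask(self):
        boxes = find_kidney_rois(np.zeros((10, 10, 10), dtype=np.int16), (1, 1, 1))
        assert boxes == []

    def test_keeps_two_largest(self):
        mask = np.zeros((30, 60, 60), dtype=np.int16)
        mask[2:28, 5:25, 5:25] = 1
        mask[2:28, 5:25, 35:55] = 1
        mask[2:10, 28:32, 28:32] = 1  # smaller third blob above threshold
        boxes = find_kidney_rois(mask, (1.0, 1.0, 1.0), crop_yx=(24, 24), min_volume_mm3=10.0)
        assert len(boxes) == 2


class TestCropRestoreRoi:
    def test_interior_exact(self, rng):
        arr = rng.normal(size=(20, 50, 50))
        box = RoiBox(z0=4, z1=12, y0=10, x0=20, size_yx=(16, 16))
        sub = crop_roi(arr, box)
        np.testing.assert_array_equal(sub, arr[4:12, 10:26, 20:36])

    def test_edge_padding_roundtrip(self, rng):
        arr = rng.integers(0, 3, size=(10, 20, 20)).astype(np.int16)
        box = RoiBox(z0=0, z1=8, y0=-4, x0=12, size_yx=(16, 16))
        sub = crop_roi(arr, box)
        assert sub.shape == (8, 16, 16)
        restored = restore_roi([sub], [box], (10, 20, 20))
        # all in-image voxels of the box must be re-placed exactly
        np.testing.assert_array_equal(restored[0:8, 0:12, 12:20], arr[0:8, 0:12, 12:20])

    def test_label_value_set_preserved(self, rng):
        arr = rng.integers(0, 3, size=(10, 30, 30)).astype(np.int16)
        box = RoiBox(z0=2, z1=9, y0=5, x0=5, size_yx=(12, 12))
        assert set(np.unique(crop_roi(arr, box))) <= {0, 1, 2}

    def test_restore_all_background(self):
        box = RoiBox(z0=0, z1=4, y0=0, x0=0, size_yx=(8, 8))
        out = restore_roi([np.zeros((4, 8, 8), dtype=np.int16)], [box], (6, 10, 10))
        assert not out.any()

    def test_two_disjoint_rois_union(self):
        b1 = RoiBox(z0=0, z1=2, y0=0, x0=0, size_yx=(4, 4))
        b2 = RoiBox(z0=4, z1=6, y0=4, x0=4, size_yx=(4, 4))
        p1 = np.full((2, 4, 4), 1, dtype=np.int16)
        p2 = np.full((2, 4, 4), 2, dtype=np.int16)
        out = restore_roi([p1, p2], [b1, b2], (8, 8, 8))
        assert (out[0:2, 0:4, 0:4] == 1).all()
        assert (out[4:6, 4:8, 4:8] == 2).all()
        assert out.sum() == 1 * 32 + 2 * 32

    def test_overlap_precedence_stone_wins(self):
        b1 = RoiBox(z0=0, z1=2, y0=0, x0=0, size_yx=(4, 4))
        b2 = RoiBox(z0=0, z1=2, y0=0, x0=0, size_yx=(4, 4))
        p1 = np.full((2, 4, 4), 1, dtype=np.int16)
        p2 = np.full((2, 4, 4), 2, dtype=np.int16)
        out = restore_roi([p1, p2], [b1, b2], (4, 4, 4))
        assert (out[0:2, 0:4, 0:4] == 2).all()

    def test_inconsistent_box_raises(self):
        box = RoiBox(z0=0, z1=12, y0=0, x0=0, size_yx=(4, 4))
        with pytest.raises(ValueError):
            restore_roi([np.zeros((12, 4, 4), dtype=np.int16)], [box], (6, 8, 8))


def test_full_geometry_roundtrip_identity_scorer(rng):
    """compose(center_crop, clip, stitch, uncrop) reproduces in-crop scores."""
    for nz, ny in ((100, 70), (96, 64), (40, 32)):
        arr = rng.normal(size=(nz, ny, ny)).astype(np.float32)
        spec = PatchSpec(crop_xy=(48, 48), cube_len=96, stride=48)
        cropped, off = center_crop_xy(arr, spec.crop_xy)
        grid = clip_z_cubes(cropped, spec)
        stitched = stitch_cubes(grid)
        back = uncrop_xy(stitched, off, (ny, ny))
        oy, ox = off
        np.testing.assert_allclose(
            back[:, oy : oy + 48, ox : ox + 48],
            arr[:, oy : oy + 48, ox : ox + 48],
            atol=1e-6,
        )
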