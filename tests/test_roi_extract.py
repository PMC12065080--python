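"""Extraction operators: bounding cubes, slice selection against exhaustive
per-slice oracles, scenario masking, and the dispatch contract."""

import numpy as np
import pytest

from conftest import sphere_mask
from periroi.io_volumes import ImageVolume, MaskVolume
from periroi.roi_extract import (
    MODES,
    SCENARIOS,
    RoiSpec,
    apply_scenario,
    bounding_cube,
    effective_mask,
    extract,
    extract_25d1,
    extract_25d2,
    extract_25d3,
    extract_2d,
    extract_3d,
)

SPEC32 = dict(out_size=32, out_size_3d=16)


def symmetric_sphere_case(n=17, radius=5):
    """Spherically symmetric intensity + digital ball mask."""
    c = n // 2
    grids = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    d2 = sum((g - c) ** 2 for g in grids)
    vol = ImageVolume(data=np.exp(-d2 / (2.0 * radius**2)))
    mask = MaskVolume(data=d2 <= radius**2)
    return vol, mask


def slice_area_argmax(mask, axis):
    """Exhaustive per-slice in-mask area scan; ties -> lower index."""
    best, best_area = None, -1
    for i in range(mask.shape[axis]):
        area = int(np.take(mask.data, i, axis=axis).sum())
        if area > best_area:
            best, best_area = i, area
    return best


class TestBoundingCube:
    def test_single_voxel(self):
        m = MaskVolume(data=np.zeros((11, 11, 11)))
        m.data[5, 5, 5] = 1
        b = bounding_cube(MaskVolume(data=m.data), pad_vox=0)
        assert b.lo == (5, 5, 5) and b.hi == (6, 6, 6) and b.is_cube

    def test_sphere_side_matches_index_scan(self):
        m = sphere_mask((16, 16, 16), (8, 8, 8), 3)
        b = bounding_cube(m)
        pos = np.argwhere(m.data)
        per_axis = pos.max(axis=0) - pos.min(axis=0) + 1  # direct min/max scan
        assert b.sides == (7, 7, 7)
        assert max(per_axis) == 7

    def test_corner_mask_clamped_not_cube(self):
        data = np.zeros((10, 10, 10))
        data[0:2, 0:5, 0:5] = 1
        b = bounding_cube(MaskVolume(data=data))
        assert not b.is_cube
        assert b.lo[0] == 0 and b.sides[0] < 5

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            bounding_cube(MaskVolume(data=np.zeros((4, 4, 4))))


class TestApplyScenario:
    def test_roi_original_identity(self, random_volume, center_sphere):
        spec = RoiSpec(scenario="ROI_original", **SPEC32)
        out = apply_scenario(random_volume, center_sphere, spec)
        np.testing.assert_array_equal(out.data, random_volume.data)

    def test_roi_only_all_ones_mask(self, random_volume):
        ones = MaskVolume(data=np.ones((16, 16, 16)))
        spec = RoiSpec(scenario="ROI_only", **SPEC32)
        out = apply_scenario(random_volume, ones, spec)
        np.testing.assert_array_equal(out.data, random_volume.data)

    def test_roi_only_outside_sum_is_fill_times_count(self, random_volume, center_sphere):
        spec = RoiSpec(scenario="ROI_only", fill_value=-3.5, **SPEC32)
        out = apply_scenario(random_volume, center_sphere, spec)
        outside = center_sphere.data == 0
        assert out.data[outside].sum() == pytest.approx(-3.5 * outside.sum())
        np.testing.assert_array_equal(
            out.data[~outside], random_volume.data[~outside]
        )


class Test25D1:
    def test_sphere_channels_identical_up_to_transpose(self):
        vol, mask = symmetric_sphere_case()
        spec = RoiSpec(mode="2.5D1", scenario="ROI_only", **SPEC32)
        masked = apply_scenario(vol, mask, spec)
        ext = extract_25d1(masked, mask, spec)
        ax, co, sa = ext.crops
        np.testing.assert_allclose(ax, co, atol=1e-12)
        np.testing.assert_allclose(ax, sa.T, atol=1e-12)
        sums = ext.sample.sum(axis=(1, 2))
        np.testing.assert_allclose(sums, sums[0], atol=1e-6)

    def test_crops_bitmatch_direct_indexing(self, rng):
        vol = ImageVolume(data=rng.normal(size=(9, 9, 9)))
        data = np.zeros((9, 9, 9))
        data[2:7, 3:8, 1:6] = 1
        mask = MaskVolume(data=data)
        spec = RoiSpec(mode="2.5D1", **SPEC32)
        ext = extract_25d1(vol, mask, spec)
        b = bounding_cube(mask)
        cz, cy, cx = (4, 5, 3)  # mean of ranges 2..6, 3..7, 1..5
        assert ext.slice_indices == {"axial": cz, "coronal": cy, "sagittal": cx}
        (z0, y0, x0), (z1, y1, x1) = b.lo, b.hi
        np.testing.assert_array_equal(ext.crops[0], vol.data[cz, y0:y1, x0:x1])
        np.testing.assert_array_equal(ext.crops[1], vol.data[z0:z1, cy, x0:x1])
        np.testing.assert_array_equal(ext.crops[2], vol.data[z0:z1, y0:y1, cx])

    def test_centroid_rounds_half_down(self, rng):
        vol = ImageVolume(data=rng.normal(size=(6, 6, 6)))
        data = np.zeros((6, 6, 6))
        data[2, 2, 2] = data[2, 2, 3] = 1  # centroid x = 2.5 -> 2
        ext = extract_25d1(vol, MaskVolume(data=data), RoiSpec(mode="2.5D1", **SPEC32))
        assert ext.slice_indices == {"axial": 2, "coronal": 2, "sagittal": 2}


class Test25D2:
    def test_single_slice_mask_clamps_to_it(self, rng):
        vol = ImageVolume(data=rng.normal(size=(12, 12, 12)))
        data = np.zeros((12, 12, 12))
        data[5, 3:9, 3:9] = 1
        ext = extract_25d2(vol, MaskVolume(data=data), RoiSpec(mode="2.5D2", **SPEC32))
        assert ext.slice_indices == {"lower": 5, "central": 5, "upper": 5}
        assert ext.notes["clamped"]
        np.testing.assert_array_equal(ext.crops[0], ext.crops[1])
        np.testing.assert_array_equal(ext.crops[1], ext.crops[2])

    def test_central_slice_is_area_argmax(self, rng):
        # ellipsoid with max cross-section off the volume center
        grids = np.meshgrid(*[np.arange(20)] * 3, indexing="ij")
        ell = (
            ((grids[0] - 8) / 5.0) ** 2
            + ((grids[1] - 10) / 3.0) ** 2
            + ((grids[2] - 10) / 4.0) ** 2
        ) <= 1.0
        mask = MaskVolume(data=ell)
        vol = ImageVolume(data=rng.normal(size=(20, 20, 20)))
        ext = extract_25d2(vol, mask, RoiSpec(mode="2.5D2", **SPEC32))
        assert ext.slice_indices["central"] == slice_area_argmax(mask, 0) == 8

    def test_offset_arithmetic(self, rng):
        # 7-slice lesion centered at z=10 with peak area at the center
        data = np.zeros((21, 21, 21))
        for dz in range(-3, 4):
            half = 5 - abs(dz)
            data[10 + dz, 10 - half : 10 + half, 10 - half : 10 + half] = 1
        vol = ImageVolume(data=rng.normal(size=(21, 21, 21)))
        ext = extract_25d2(
            vol, MaskVolume(data=data), RoiSpec(mode="2.5D2", slice_offset=2, **SPEC32)
        )
        assert (ext.slice_indices["lower"], ext.slice_indices["central"],
                ext.slice_indices["upper"]) == (8, 10, 12)
        assert not ext.notes["clamped"]


class Test25D3:
    def test_tilted_ellipsoid_matches_per_view_scan(self, rng):
        grids = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        # sheared ellipsoid: per-view argmax differs across views
        ell = (
            ((grids[0] - 10 + 0.4 * (grids[1] - 12)) / 5.0) ** 2
            + ((grids[1] - 12) / 4.0) ** 2
            + ((grids[2] - 13) / 3.0) ** 2
        ) <= 1.0
        mask = MaskVolume(data=ell)
        vol = ImageVolume(data=rng.normal(size=(24, 24, 24)))
        ext = extract_25d3(vol, mask, RoiSpec(mode="2.5D3", **SPEC32))
        assert ext.slice_indices["axial"] == slice_area_argmax(mask, 0)
        assert ext.slice_indices["coronal"] == slice_area_argmax(mask, 1)
        assert ext.slice_indices["sagittal"] == slice_area_argmax(mask, 2)

    def test_sphere_same_planes_as_centroid_mode(self):
        vol, mask = symmetric_sphere_case()
        spec3 = RoiSpec(mode="2.5D3", **SPEC32)
        spec1 = RoiSpec(mode="2.5D1", **SPEC32)
        assert extract_25d3(vol, mask, spec3).slice_indices == extract_25d1(
            vol, mask, spec1
        ).slice_indices

    def test_area_tie_takes_lower_index(self, rng):
        data = np.zeros((10, 10, 10))
        data[3, 2:7, 2:7] = 1
        data[6, 1:6, 1:6] = 1  # same area 25, higher index
        vol = ImageVolume(data=rng.normal(size=(10, 10, 10)))
        ext = extract_25d3(vol, MaskVolume(data=data), RoiSpec(mode="2.5D3", **SPEC32))
        assert ext.slice_indices["axial"] == 3


class Test2D:
    def test_three_identical_channels_and_oracle_index(self, rng, center_sphere):
        vol = ImageVolume(data=rng.normal(size=(16, 16, 16)))
        ext = extract_2d(vol, center_sphere, RoiSpec(mode="2D", **SPEC32))
        np.testing.assert_array_equal(ext.sample[0], ext.sample[1])
        np.testing.assert_array_equal(ext.sample[0], ext.sample[2])
        assert ext.slice_indices["axial"] == slice_area_argmax(center_sphere, 0)

    def test_one_voxel_mask_constant_image(self, rng):
        vol = ImageVolume(data=rng.normal(size=(8, 8, 8)))
        data = np.zeros((8, 8, 8))
        data[4, 4, 4] = 1
        ext = extract_2d(vol, MaskVolume(data=data), RoiSpec(mode="2D", **SPEC32))
        assert ext.sample.shape == (3, 32, 32)
        np.testing.assert_allclose(ext.sample[0], vol.data[4, 4, 4], atol=1e-12)


class Test3D:
    def test_identity_crop_when_sizes_match(self, rng):
        vol = ImageVolume(data=rng.normal(size=(12, 12, 12)))
        data = np.zeros((12, 12, 12))
        data[2:10, 2:10, 2:10] = 1
        spec = RoiSpec(mode="3D", out_size=32, out_size_3d=8)
        ext = extract_3d(vol, MaskVolume(data=data), spec)
        np.testing.assert_array_equal(ext.sample[0], vol.data[2:10, 2:10, 2:10])

    def test_patch_mean_close_to_crop_mean(self):
        vol, mask = symmetric_sphere_case(n=21, radius=6)
        ext = extract_3d(vol, mask, RoiSpec(mode="3D", out_size=32, out_size_3d=16))
        crop_mean = ext.crops[0].mean()
        assert abs(ext.sample.mean() - crop_mean) / abs(crop_mean) < 0.02

    def test_roi_only_fill_outside_mask(self, rng):
        vol, mask = symmetric_sphere_case(n=15, radius=4)
        spec = RoiSpec(mode="3D", scenario="ROI_only", fill_value=0.0, out_size_3d=16)
        masked = apply_scenario(vol, mask, spec)
        ext = extract_3d(masked, mask, spec)
        # voxels of the pre-resize crop outside the mask are exactly fill
        b = ext.bbox
        crop_mask = mask.data[b.slices()]
        assert np.all(ext.crops[0][crop_mask == 0] == 0.0)


class TestDispatch:
    def test_effective_mask_radius_zero_and_monotone(self, center_sphere):
        m0 = effective_mask(center_sphere, 0.0)
        np.testing.assert_array_equal(m0.data, center_sphere.data)
        m4 = effective_mask(center_sphere, 4.0)
        assert np.all(center_sphere.data <= m4.data)

    def test_provenance_and_grid_closure(self, rng):
        vol = ImageVolume(data=rng.normal(size=(24, 24, 24)))
        mask = sphere_mask((24, 24, 24), (12, 12, 12), 4)
        spec = RoiSpec(mode="2.5D1", radius_mm=4.0, scenario="ROI_original", **SPEC32)
        ext = extract(vol, mask, spec, case_id="c1")
        assert ext.spec.radius_mm == 4.0 and ext.spec.scenario == "ROI_original"
        assert ext.case_id == "c1"

        n = 0
        for mode in MODES:
            for r in (0.0, 2.0):
                for scen in SCENARIOS:
                    s = RoiSpec(mode=mode, radius_mm=r, scenario=scen, **SPEC32)
                    e = extract(vol, mask, s)
                    assert np.all(np.isfinite(e.sample))
                    n += 1
        assert n == 20

    def test_scenarios_share_framing_and_differ_only_outside_mask(self, rng):
        vol = ImageVolume(data=rng.normal(size=(24, 24, 24)))
        mask = sphere_mask((24, 24, 24), (12, 12, 12), 4)
        for mode in MODES:
            so = RoiSpec(mode=mode, radius_mm=0.0, scenario="ROI_only", **SPEC32)
            sr = RoiSpec(mode=mode, radius_mm=0.0, scenario="ROI_original", **SPEC32)
            eo, er = extract(vol, mask, so), extract(vol, mask, sr)
            assert eo.bbox == er.bbox
            assert eo.slice_indices == er.slice_indices
            # voxelwise difference restricted to the mask is zero (pre-resize)
            if mode == "3D":
                crop_mask = mask.data[eo.bbox.slices()]
                diff = eo.crops[0] - er.crops[0]
                assert np.all(diff[crop_mask > 0] == 0)
            else:
                assert np.any(eo.crops[0] != er.crops[0])

    def test_deterministic(self, rng, center_sphere):
        vol = ImageVolume(data=rng.normal(size=(16, 16, 16)))
        spec = RoiSpec(mode="2.5D2", radius_mm=2.0, scenario="ROI_only", **SPEC32)
        a = extract(vol, center_sphere, spec)
        b = extract(vol, center_sphere, spec)
        np.testing.assert_array_equal(a.sample, b.sample)
        for ca, cb in zip(a.crops, b.crops):
            np.testing.assert_array_equal(ca, cb)
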