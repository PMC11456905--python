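import numpy as np
import pytest

import liverspare as ls
from liverspare.segmentation import EmptyROIError, uncrop

from conftest import small_phantom_config
from oracles import brute_bbox, brute_block_mean_inplane, oracle_segment_flv


def _img(arr, spacing=(1.1, 1.1, 8.0)):
    return ls.VoxelImage(np.asarray(arr, dtype=float), spacing)


class TestDownsample:
    def test_constant_image_spacing_doubles(self):
        img = _img(np.full((8, 8, 4), 3.3))
        out = ls.downsample_inplane(img, 2)
        assert out.shape == (4, 4, 4)
        assert np.allclose(out.data, 3.3)
        assert out.spacing == pytest.approx((2.2, 2.2, 8.0))

    def test_factor_one_is_identity(self):
        img = _img(np.random.default_rng(0).normal(size=(6, 6, 3)))
        out = ls.downsample_inplane(img, 1)
        assert np.array_equal(out.data, img.data)
        assert out.spacing == img.spacing

    def test_checkerboard_becomes_half(self):
        cb = np.indices((8, 8, 2)).sum(axis=0) % 2
        out = ls.downsample_inplane(_img(cb), 2)
        assert np.allclose(out.data, 0.5)

    def test_odd_dims_edge_padded_and_recorded(self, rng):
        arr = rng.normal(size=(7, 9, 3))
        out = ls.downsample_inplane(_img(arr), 2)
        assert out.shape == (4, 5, 3)
        assert out.meta["inplane_padding"] == (1, 1)
        assert np.allclose(out.data, brute_block_mean_inplane(arr, 2))

    def test_matches_brute_force(self, rng):
        arr = rng.normal(size=(12, 12, 5))
        out = ls.downsample_inplane(_img(arr), 3)
        assert np.allclose(out.data, brute_block_mean_inplane(arr, 3))

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            ls.downsample_inplane(_img(np.zeros((4, 4, 2))), 0)


class TestCrop:
    def test_full_roi_identity(self, rng):
        img = _img(rng.normal(size=(5, 6, 4)))
        out = ls.crop_to_roi(img, np.ones((5, 6, 4), bool))
        assert np.array_equal(out.data, img.data)
        assert out.meta["crop_offset"] == (0, 0, 0)

    def test_single_voxel(self, rng):
        img = _img(rng.normal(size=(5, 6, 4)))
        roi = np.zeros((5, 6, 4), bool)
        roi[2, 3, 1] = True
        out = ls.crop_to_roi(img, roi)
        assert out.shape == (1, 1, 1)
        assert out.data[0, 0, 0] == img.data[2, 3, 1]
        # origin shifted so physical position is preserved
        assert out.origin == pytest.approx(
            tuple(img.origin[a] + [2, 3, 1][a] * img.spacing[a] for a in range(3))
        )

    def test_ellipsoid_bbox_matches_exhaustive_scan(self, rng):
        x, y, z = np.meshgrid(*[np.arange(n) for n in (20, 22, 12)], indexing="ij")
        roi = ((x - 9) / 6.0) ** 2 + ((y - 11) / 7.0) ** 2 + ((z - 5) / 4.0) ** 2 <= 1
        img = _img(rng.normal(size=roi.shape))
        out = ls.crop_to_roi(img, roi)
        lo, hi = brute_bbox(roi)
        assert out.meta["crop_offset"] == lo
        assert out.shape == tuple(h - l for l, h in zip(lo, hi))

    def test_empty_roi_raises(self):
        with pytest.raises(EmptyROIError):
            ls.crop_to_roi(_img(np.zeros((4, 4, 2))), np.zeros((4, 4, 2), bool))

    def test_uncrop_restores_frame(self):
        mask = np.ones((2, 2, 1), bool)
        full = uncrop(mask, (5, 5, 3), (1, 2, 1))
        assert full.sum() == 4
        assert full[1:3, 2:4, 1].all()


class TestThreshold:
    def test_uniform_functional_liver(self):
        roi = np.zeros((6, 6, 3), bool)
        roi[1:5, 1:5, :] = True
        out = ls.threshold_functional(_img(np.full((6, 6, 3), 700.0)), roi)
        assert np.array_equal(out, roi)

    def test_exactly_at_threshold_excluded(self):
        roi = np.ones((4, 4, 2), bool)
        out = ls.threshold_functional(_img(np.full((4, 4, 2), 800.0)), roi)
        assert not out.any()

    def test_count_matches_exhaustive_scan(self, rng):
        vals = rng.normal(800, 60, size=(10, 10, 4))
        roi = rng.random((10, 10, 4)) > 0.3
        out = ls.threshold_functional(_img(vals), roi, 800.0)
        count = sum(
            1
            for i in range(10)
            for j in range(10)
            for k in range(4)
            if roi[i, j, k] and vals[i, j, k] < 800.0
        )
        assert out.sum() == count

    @pytest.mark.parametrize("pair", [(750.0, 800.0), (800.0, 850.0)])
    def test_monotone_in_threshold(self, rng, pair):
        vals = rng.normal(800, 60, size=(12, 12, 4))
        roi = np.ones(vals.shape, bool)
        lo = ls.threshold_functional(_img(vals), roi, pair[0])
        hi = ls.threshold_functional(_img(vals), roi, pair[1])
        assert not (lo & ~hi).any()  # lower-threshold mask is a subset


class TestSmoothAndMedian:
    def test_mask_equal_scope_is_preserved(self):
        scope = np.zeros((20, 20, 6), bool)
        scope[4:16, 4:16, 1:5] = True
        out = ls.smooth_and_median(scope, scope, ls.SegmentationParams())
        assert np.array_equal(out, scope)

    def test_sigma_zero_is_passthrough(self, rng):
        scope = np.ones((12, 12, 4), bool)
        mask = rng.random(scope.shape) > 0.5
        params = ls.SegmentationParams(smoothing_sigma=0.0)
        out = ls.smooth_and_median(mask, scope, params)
        assert np.array_equal(out, mask)

    def test_empty_mask_empty_output(self):
        scope = np.ones((10, 10, 3), bool)
        out = ls.smooth_and_median(np.zeros_like(scope), scope, ls.SegmentationParams())
        assert not out.any()

    def test_speckle_removed_when_functional_majority(self):
        # when most of the scope is functional the median sits high, so an
        # isolated functional voxel far from the bulk falls below it
        scope = np.zeros((48, 48, 4), bool)
        scope[2:46, 2:46, :] = True
        mask = np.zeros_like(scope)
        mask[4:32, 4:32, :] = True  # dominant functional region
        mask[42:43, 42:43, :] = True  # isolated voxel column
        out = ls.smooth_and_median(mask, scope, ls.SegmentationParams())
        assert out[18, 18, 1]  # core of the big region survives
        assert not out[42, 42, 1]  # speckle removed
        assert not (out & ~scope).any()

    def test_two_blob_chain_matches_dense_oracle(self):
        # 30 mm and 3 mm functional blobs: the outcome of the median
        # re-threshold is fixed by the dense oracle chain
        from oracles import oracle_segment_flv

        sp = (1.1, 1.1, 8.0)
        n = 96
        x, y, _ = np.meshgrid(
            (np.arange(n) + 0.5) * sp[0],
            (np.arange(n) + 0.5) * sp[1],
            (np.arange(8) + 0.5) * sp[2],
            indexing="ij",
        )
        liver = ((x - 52) / 45) ** 2 + ((y - 52) / 45) ** 2 <= 1
        fov = np.ones_like(liver, bool)
        ct1 = np.full(liver.shape, 950.0)
        ct1[((x - 35) ** 2 + (y - 35) ** 2) <= 15**2] = 700.0
        ct1[((x - 75) ** 2 + (y - 75) ** 2) <= 1.5**2] = 700.0
        res = ls.segment_flv(ls.VoxelImage(ct1, sp), liver, fov)
        expected = oracle_segment_flv(ct1, liver, fov, sp)
        assert np.array_equal(res.flv_working.data, expected)
        assert res.flv_working.data[int(35 / 2.2), int(35 / 2.2), 4]  # large blob core kept

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            ls.SegmentationParams(smoothing_sigma=-1.0)


class TestSegmentFLV:
    def _uniform_patient(self, value):
        p = ls.generate_patient(small_phantom_config())
        ct1 = p.ct1_map.copy(data=np.full(p.ct1_map.shape, float(value)))
        return p, ct1

    def test_uniform_700_gives_full_roi(self):
        p, ct1 = self._uniform_patient(700.0)
        res = ls.segment_flv(ct1, p.structures["liver"], p.structures["fov"])
        from liverspare.grids import downsample_mask_inplane

        liver = downsample_mask_inplane(p.structures.image("liver"), 2).data
        fov = downsample_mask_inplane(p.structures.image("fov"), 2).data
        assert np.array_equal(res.flv_working.data, liver & fov)

    def test_uniform_900_gives_empty(self):
        p, ct1 = self._uniform_patient(900.0)
        res = ls.segment_flv(ct1, p.structures["liver"], p.structures["fov"])
        assert not res.flv_working.data.any()

    def test_exactly_800_excluded(self):
        p, ct1 = self._uniform_patient(800.0)
        res = ls.segment_flv(ct1, p.structures["liver"], p.structures["fov"])
        assert not res.flv_working.data.any()

    def test_flv_contained_in_roi(self, small_patient):
        p = small_patient
        res = ls.segment_flv(p.ct1_map, p.structures["liver"], p.structures["fov"])
        from liverspare.grids import downsample_mask_inplane

        liver = downsample_mask_inplane(p.structures.image("liver"), 2).data
        fov = downsample_mask_inplane(p.structures.image("fov"), 2).data
        assert not (res.flv_working.data & ~(liver & fov)).any()

    def test_empty_roi_raises(self, small_patient):
        p = small_patient
        with pytest.raises(EmptyROIError):
            ls.segment_flv(
                p.ct1_map, p.structures["liver"], np.zeros(p.ct1_map.shape, bool)
            )

    def test_matches_dense_oracle_on_random_phantom(self):
        cfg = ls.PhantomConfig(
            grid_shape=(32, 32, 8),
            spacing_mm=(2.0, 2.0, 4.0),
            gtv_radius_mm=4.0,
            gtv_offset_mm=(2.0, 1.0, -2.0),
            correlation_length_mm=8.0,
            seed=42,
        )
        p = ls.generate_patient(cfg)
        res = ls.segment_flv(p.ct1_map, p.structures["liver"], p.structures["fov"])
        expected = oracle_segment_flv(
            p.ct1_map.data, p.structures["liver"], p.structures["fov"], cfg.spacing_mm
        )
        assert np.array_equal(res.flv_working.data, expected)

    def test_smoothing_conserves_interior_mean(self):
        # a normalized symmetric kernel reproduces a linear ramp exactly away
        # from the boundary, so the interior mean is conserved
        from scipy import ndimage

        x = np.arange(80)[:, None, None] * np.ones((80, 80, 4))
        field = 5.0 + 0.01 * x
        sm = ndimage.gaussian_filter(field, (4, 4, 0), mode="constant", truncate=6.0)
        interior = (slice(30, 50), slice(30, 50), slice(0, 4))
        rel = abs(sm[interior].mean() - field[interior].mean()) / field[interior].mean()
        assert rel < 0.005
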