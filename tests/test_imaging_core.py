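"""Geometric and intensity primitives: resampling, smoothing, masked stats."""

import numpy as np
import pytest
from scipy import special

from atrspect.imaging_core import (
    BinaryVOI,
    Grid,
    Volume,
    centered_grid,
    fwhm_to_sigma,
    gaussian_smooth,
    grids_compatible,
    masked_mean,
    resample,
)

from conftest import full_mask, random_volume


class TestGrid:
    def test_centered_grid_puts_world_origin_at_volume_center(self):
        g = centered_grid((17, 17, 17), 2.0)
        center = g.voxel_to_world(np.array([8.0, 8.0, 8.0]))
        np.testing.assert_allclose(center, 0.0, atol=1e-12)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            Grid((0, 4, 4), np.eye(4))

    def test_singular_affine_rejected(self):
        aff = np.eye(4)
        aff[0, 0] = 0.0
        with pytest.raises(ValueError, match="non-invertible"):
            Grid((4, 4, 4), aff)

    def test_world_voxel_round_trip(self, rng):
        g = centered_grid((10, 12, 14), (1.5, 2.0, 2.5))
        ijk = rng.random((20, 3)) * 9
        np.testing.assert_allclose(g.world_to_voxel(g.voxel_to_world(ijk)), ijk)


class TestVolume:
    def test_non_finite_rejected(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[3, 3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            Volume(data, small_grid)

    def test_shape_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError):
            Volume(np.zeros((4, 4, 4)), small_grid)

    def test_grid_compatibility_tolerance(self, small_grid):
        aff = small_grid.affine.copy()
        aff[0, 3] += 1e-8
        assert grids_compatible(small_grid, Grid(small_grid.shape, aff))
        aff[0, 3] += 1e-3
        assert not grids_compatible(small_grid, Grid(small_grid.shape, aff))


class TestResample:
    def test_identity_transform_preserves_volume(self, small_grid, rng):
        vol = random_volume(small_grid, rng)
        out = resample(vol, small_grid)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_integer_voxel_translation_moves_delta(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[8, 8, 8] = 5.0
        vol = Volume(data, small_grid)
        shift = np.array([2.0, 0.0, 0.0]) * small_grid.spacing[0]  # 2 voxels in x
        out = resample(vol, small_grid, transform=lambda xyz: xyz + shift)
        # pull-back: output at index i samples source at i+2
        assert out.data[6, 8, 8] == pytest.approx(5.0)
        assert out.data.sum() == pytest.approx(5.0)

    def test_half_voxel_translation_splits_delta_linearly(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[8, 8, 8] = 4.0
        vol = Volume(data, small_grid)
        shift = np.array([0.5 * small_grid.spacing[0], 0.0, 0.0])
        out = resample(vol, small_grid, transform=lambda xyz: xyz + shift)
        # linear interpolation: two voxels at half the original value
        assert out.data[7, 8, 8] == pytest.approx(2.0)
        assert out.data[8, 8, 8] == pytest.approx(2.0)
        assert np.count_nonzero(out.data) == 2

    def test_nearest_interpolation_preserves_labels(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[4:8, 4:8, 4:8] = 3.0
        vol = Volume(data, small_grid)
        out = resample(vol, small_grid, interpolation="nearest")
        assert set(np.unique(out.data)) <= {0.0, 3.0}

    def test_out_of_field_fills_zero(self, small_grid, rng):
        vol = random_volume(small_grid, rng)
        big = np.array([1000.0, 0.0, 0.0])
        out = resample(vol, small_grid, transform=lambda xyz: xyz + big)
        assert np.all(out.data == 0)

    def test_forward_inverse_round_trip_on_smooth_volume(self):
        grid = centered_grid((32, 32, 32), 2.0)
        w = grid.world_coordinates()
        data = np.exp(-((w**2).sum(axis=-1)) / (2 * 15.0**2))
        vol = Volume(data, grid)
        shift = np.array([3.3, -2.1, 1.7])
        fwd = resample(vol, grid, transform=lambda x: x + shift)
        back = resample(fwd, grid, transform=lambda x: x - shift)
        core = (slice(4, -4),) * 3
        rms = np.sqrt(np.mean((back.data[core] - vol.data[core]) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(vol.data[core] ** 2))

    def test_unknown_interpolation_rejected(self, small_grid, rng):
        with pytest.raises(ValueError, match="interpolation"):
            resample(random_volume(small_grid, rng), small_grid, interpolation="cubic")


class TestGaussianSmooth:
    def test_constant_volume_unchanged(self, small_grid):
        vol = Volume(np.full(small_grid.shape, 3.5), small_grid)
        # constant-mode boundary loses mass at edges; check the interior
        out = gaussian_smooth(vol, 4.0)
        assert out.data[8, 8, 8] == pytest.approx(3.5, rel=1e-6)

    def test_delta_peak_matches_separable_kernel(self):
        grid = centered_grid((33, 33, 33), 2.0)
        data = np.zeros(grid.shape)
        data[16, 16, 16] = 7.0
        out = gaussian_smooth(Volume(data, grid), 8.0)
        # discrete separable kernel central weight, one axis
        sigma_vox = fwhm_to_sigma(8.0) / 2.0
        x = np.arange(-16, 17)
        k = np.exp(-(x**2) / (2 * sigma_vox**2))
        k /= k.sum()
        expected_peak = 7.0 * k[16] ** 3
        assert out.data[16, 16, 16] == pytest.approx(expected_peak, rel=1e-3)
        assert out.data.sum() == pytest.approx(7.0, rel=1e-3)

    def test_edge_response_is_half_maximum_at_face(self):
        # a large homogeneous cube: the smoothed value at a face center is
        # given by the error-function edge response, ~50% of the plateau
        grid = centered_grid((40, 40, 40), 2.0)
        data = np.zeros(grid.shape)
        data[8:32, 8:32, 8:32] = 100.0
        out = gaussian_smooth(Volume(data, grid), 8.0)
        # face at index 8: half-maximum sits half a voxel outside the first
        # filled sample; compare against the erf prediction there
        sigma_mm = fwhm_to_sigma(8.0)
        offset_mm = 0.5 * 2.0  # half a voxel
        expected = 100.0 * 0.5 * (1 + special.erf(offset_mm / (sigma_mm * np.sqrt(2))))
        assert out.data[8, 20, 20] == pytest.approx(expected, rel=0.02)

    def test_linearity(self, small_grid, rng):
        a = random_volume(small_grid, rng)
        b = random_volume(small_grid, rng)
        lhs = gaussian_smooth(Volume(2 * a.data + 3 * b.data, small_grid), 5.0)
        rhs = 2 * gaussian_smooth(a, 5.0).data + 3 * gaussian_smooth(b, 5.0).data
        np.testing.assert_allclose(lhs.data, rhs, atol=1e-12)

    def test_sub_voxel_fwhm_passes_through_with_warning(self, small_grid, rng):
        vol = random_volume(small_grid, rng)
        with pytest.warns(UserWarning, match="smoothing skipped"):
            out = gaussian_smooth(vol, 0.01)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_nonpositive_fwhm_rejected(self, small_grid, rng):
        with pytest.raises(ValueError):
            gaussian_smooth(random_volume(small_grid, rng), 0.0)


class TestMaskedMean:
    def test_uniform_volume_gives_constant(self, small_grid):
        vol = Volume(np.full(small_grid.shape, 7.0), small_grid)
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        assert masked_mean(vol, BinaryVOI(mask, small_grid)) == 7.0

    def test_three_voxel_mean(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[0, 0, 0], data[1, 0, 0], data[2, 0, 0] = 1.0, 2.0, 3.0
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[:3, 0, 0] = True
        assert masked_mean(Volume(data, small_grid), BinaryVOI(mask, small_grid)) == 2.0

    def test_full_mask_equals_global_mean(self, small_grid, rng):
        vol = random_volume(small_grid, rng)
        assert masked_mean(vol, full_mask(small_grid)) == pytest.approx(
            vol.data.mean(), abs=1e-14
        )

    def test_permutation_invariance_within_mask(self, small_grid, rng):
        vol = random_volume(small_grid, rng)
        mask = rng.random(small_grid.shape) > 0.6
        voi = BinaryVOI(mask, small_grid)
        before = masked_mean(vol, voi)
        vals = vol.data[mask]
        shuffled = vol.data.copy()
        shuffled[mask] = rng.permutation(vals)
        assert masked_mean(Volume(shuffled, small_grid), voi) == pytest.approx(before)

    def test_empty_mask_is_an_error(self, small_grid, rng):
        vol = random_volume(small_grid, rng)
        with pytest.raises(ValueError, match="empty mask"):
            masked_mean(vol, BinaryVOI(np.zeros(small_grid.shape, bool), small_grid))

    def test_grid_mismatch_is_an_error(self, small_grid, rng):
        vol = random_volume(small_grid, rng)
        other = centered_grid(small_grid.shape, 3.0)
        with pytest.raises(ValueError, match="grid mismatch"):
            masked_mean(vol, BinaryVOI(np.ones(other.shape, bool), other))
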