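"""Surface masking, volume-targeted thresholding, ROI interpolation,
masked intensity density."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hcrquant.grids import Mask3D, VoxelGrid
from hcrquant.masking import (MaskingConfig, auto_threshold_to_volume,
                              build_surface_mask, interpolate_roi_mask,
                              masked_intensity_density)

NO_SPECKLE = MaskingConfig(min_component_um3=0.0, smoothing_scale_um=0.5)


def _box_channel():
    """100 a.u. inside a 10×10×10-voxel box, 0 outside; 1 µm³ voxels."""
    data = np.zeros((20, 20, 20), dtype=np.float32)
    data[5:15, 5:15, 5:15] = 100.0
    return VoxelGrid(data, spacing=(1, 1, 1), channel="ref")


class TestBuildSurfaceMask:
    def test_zero_threshold_covers_everything_positive(self):
        g = VoxelGrid(np.full((4, 8, 8), 3.0), spacing=(1, 1, 1))
        mask = build_surface_mask(g, NO_SPECKLE, threshold=0.0)
        assert mask.n_voxels == g.data.size

    def test_box_volume_recovered(self):
        g = _box_channel()
        cfg = MaskingConfig(min_component_um3=0.0, smoothing_scale_um=0.1)
        mask = build_surface_mask(g, cfg, threshold=50.0)
        assert mask.volume_um3 == pytest.approx(1000.0, rel=0.05)

    def test_threshold_above_max_gives_empty_mask_with_warning(self):
        g = _box_channel()
        with pytest.warns(UserWarning, match="empty"):
            mask = build_surface_mask(g, NO_SPECKLE, threshold=1e6)
        assert mask.is_empty() and mask.volume_um3 == 0.0

    def test_volume_monotone_in_threshold(self, rng):
        from scipy.ndimage import gaussian_filter
        data = gaussian_filter(rng.uniform(0, 100, (10, 24, 24)), 2.0)
        g = VoxelGrid(data, spacing=(1, 1, 1))
        vols = [build_surface_mask(g, NO_SPECKLE, t).volume_um3
                for t in np.linspace(0, data.max(), 12)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_component_policy_removes_speckle(self):
        data = np.zeros((10, 20, 20), dtype=np.float32)
        data[2:8, 2:12, 2:12] = 100.0   # 600 µm³ block
        data[9, 18, 18] = 100.0          # single-voxel speckle
        g = VoxelGrid(data, spacing=(1, 1, 1))
        cfg = MaskingConfig(min_component_um3=100.0, smoothing_scale_um=0.1)
        mask = build_surface_mask(g, cfg, threshold=50.0)
        assert not mask.data[9, 18, 18]
        assert mask.data[5, 5, 5]


class TestAutoThreshold:
    def test_plateau_case_returns_plateau_volume(self):
        # suprathreshold volume is 1000 µm³ for any threshold in (0, 100]
        g = _box_channel()
        cfg = MaskingConfig(volume_window_um3=(900.0, 1100.0),
                            min_component_um3=0.0, smoothing_scale_um=0.1)
        thr, mask = auto_threshold_to_volume(g, cfg)
        assert mask.volume_um3 == pytest.approx(1000.0, rel=0.02)

    def test_matches_exhaustive_scan_oracle(self, rng):
        from scipy.ndimage import gaussian_filter
        data = gaussian_filter(rng.uniform(0, 100, (8, 16, 16)), 1.5)
        g = VoxelGrid(data, spacing=(1, 1, 1))
        lo, hi = 200.0, 260.0
        cfg = MaskingConfig(volume_window_um3=(lo, hi), min_component_um3=0.0,
                            smoothing_scale_um=0.5)
        thr, mask = auto_threshold_to_volume(g, cfg)
        assert lo <= mask.volume_um3 <= hi
        # oracle: brute-force scan over every distinct smoothed value
        from scipy.ndimage import gaussian_filter as gf
        sig = 0.5 / (2 * np.sqrt(2 * np.log(2)))
        smoothed = gf(data.astype(np.float32), sigma=[sig, sig, sig])
        qualifying = [v for v in np.unique(smoothed)
                      if lo <= (smoothed >= v).sum() <= hi]
        assert qualifying, "oracle found no qualifying threshold"
        assert thr == pytest.approx(max(qualifying))

    def test_tiny_window_unique_threshold(self):
        data = np.arange(64, dtype=np.float64).reshape(4, 4, 4)
        g = VoxelGrid(data, spacing=(1, 1, 1))
        cfg = MaskingConfig(volume_window_um3=(1.0, 2.0), min_component_um3=0.0,
                            smoothing_scale_um=1e-6)
        thr, mask = auto_threshold_to_volume(g, cfg)
        assert mask.n_voxels in (1, 2)

    def test_unattainable_window_reports_nearest_volumes(self):
        g = _box_channel()  # volumes jump 0 -> 1000
        cfg = MaskingConfig(volume_window_um3=(100.0, 200.0),
                            min_component_um3=0.0, smoothing_scale_um=0.1)
        with pytest.raises(ValueError, match="nearest achievable"):
            auto_threshold_to_volume(g, cfg)


class TestInterpolateRoiMask:
    def test_identical_squares_fill_intermediate_plane(self):
        square = np.array([[5.0, 5.0], [5.0, 15.0], [15.0, 15.0], [15.0, 5.0]])
        mask = interpolate_roi_mask([(0, square), (2, square)], z_extent=3,
                                    yx_shape=(20, 20), spacing=(1, 1, 1))
        np.testing.assert_array_equal(mask.data[1], mask.data[0])
        assert mask.data[0, 10, 10]

    def test_concentric_circles_interpolate_radius(self):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        def circle(r):
            return np.stack([25 + r * np.sin(theta), 25 + r * np.cos(theta)], axis=1)
        mask = interpolate_roi_mask([(0, circle(10)), (2, circle(20))], z_extent=3,
                                    yx_shape=(50, 50), spacing=(1, 1, 1))
        r_mid = np.sqrt(mask.data[1].sum() / np.pi)
        assert r_mid == pytest.approx(15.0, abs=1.0)

    def test_planes_outside_range_copy_nearest(self):
        square = np.array([[5.0, 5.0], [5.0, 15.0], [15.0, 15.0], [15.0, 5.0]])
        mask = interpolate_roi_mask([(1, square), (3, square)], z_extent=6,
                                    yx_shape=(20, 20), spacing=(1, 1, 1))
        np.testing.assert_array_equal(mask.data[0], mask.data[1])
        np.testing.assert_array_equal(mask.data[5], mask.data[3])

    def test_single_plane_errors(self):
        square = np.array([[5.0, 5.0], [5.0, 15.0], [15.0, 15.0], [15.0, 5.0]])
        with pytest.raises(ValueError, match="two annotated"):
            interpolate_roi_mask([(0, square)], z_extent=3, yx_shape=(20, 20),
                                 spacing=(1, 1, 1))

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 10.0], [10.0, 0.0]])
        with pytest.raises(ValueError, match="self-intersecting"):
            interpolate_roi_mask([(0, bowtie), (2, bowtie)], z_extent=3,
                                 yx_shape=(20, 20), spacing=(1, 1, 1))


class TestMaskedIntensityDensity:
    def test_uniform_field(self):
        data = np.full((5, 8, 8), 5.0)
        g = VoxelGrid(data, spacing=(1, 1, 1), channel="gene")
        m = np.zeros_like(data, dtype=bool)
        m.ravel()[:200] = True
        meas = masked_intensity_density(g, Mask3D(m, spacing=(1, 1, 1)))
        assert meas.intensity_sum == pytest.approx(1000.0)
        assert meas.density == pytest.approx(5.0)
        assert meas.density * meas.volume_um3 == pytest.approx(meas.intensity_sum)

    def test_matches_naive_voxel_loop(self, rng):
        data = rng.uniform(0, 50, (6, 10, 10))
        m = rng.uniform(size=data.shape) > 0.5
        g = VoxelGrid(data, spacing=(2.5, 0.9, 0.9))
        meas = masked_intensity_density(g, Mask3D(m, spacing=(2.5, 0.9, 0.9)))
        total = 0.0
        for z in range(6):
            for y in range(10):
                for x in range(10):
                    if m[z, y, x]:
                        total += data[z, y, x]
        assert meas.intensity_sum == pytest.approx(total, rel=1e-12)

    def test_all_zero_grid_gives_zero_density(self):
        g = VoxelGrid(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        m = Mask3D(np.ones((4, 4, 4), dtype=bool), spacing=(1, 1, 1))
        assert masked_intensity_density(g, m).density == 0.0

    def test_zeroing_outside_mask_leaves_result_unchanged(self, rng):
        data = rng.uniform(0, 50, (4, 8, 8))
        m = rng.uniform(size=data.shape) > 0.3
        mask = Mask3D(m, spacing=(1, 1, 1))
        full = masked_intensity_density(VoxelGrid(data, (1, 1, 1)), mask)
        zeroed = masked_intensity_density(VoxelGrid(data * m, (1, 1, 1)), mask)
        assert full.intensity_sum == pytest.approx(zeroed.intensity_sum)

    def test_shape_mismatch_and_empty_mask_error(self, rng):
        g = VoxelGrid(rng.uniform(size=(4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="shape"):
            masked_intensity_density(
                g, Mask3D(np.ones((5, 4, 4), bool), spacing=(1, 1, 1)))
        with pytest.raises(ValueError, match="empty"):
            masked_intensity_density(
                g, Mask3D(np.zeros((4, 4, 4), bool), spacing=(1, 1, 1)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_density_linear_in_grid(self, a, b):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, (4, 6, 6))
        y = rng.uniform(0, 10, (4, 6, 6))
        m = Mask3D(rng.uniform(size=x.shape) > 0.4, spacing=(1, 1, 1))
        dens = lambda arr: np.sum(arr[m.data]) / m.volume_um3
        combo = a * x + b * y
        assert dens(combo) == pytest.approx(a * dens(x) + b * dens(y), abs=1e-9)
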