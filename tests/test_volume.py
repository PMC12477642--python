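import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmodal.volume import (
    DynamicSeries,
    IntegrationWindow,
    UptakeNotDetectedError,
    VolumeMap,
    detect_uptake_start,
    fwhm_to_sigma_vox,
    gaussian_smooth,
    group_median,
    normalize_global_mean,
    optimize_fwhm,
    sum_image,
)

VOXEL = 6.0


def series_from_means(means, times, shape=(4, 4, 4)):
    """Series whose frames are constant volumes with the given means."""
    data = np.stack([np.full(shape, m, dtype=float) for m in means], axis=-1)
    return DynamicSeries(data, np.asarray(times, dtype=float), VOXEL)


def full_mask(shape=(4, 4, 4)):
    return np.ones(shape, dtype=bool)


class TestVolumeMap:
    def test_rejects_non_3d(self):
        with pytest.raises(ValueError):
            VolumeMap(np.zeros((4, 4)), VOXEL)

    def test_rejects_nonpositive_voxel(self):
        with pytest.raises(ValueError):
            VolumeMap(np.zeros((4, 4, 4)), 0.0)


class TestDynamicSeries:
    def test_rejects_nonincreasing_times(self):
        with pytest.raises(ValueError):
            series_from_means([1, 2, 3], [0, 5, 5])

    def test_rejects_time_length_mismatch(self):
        with pytest.raises(ValueError):
            series_from_means([1, 2, 3], [0, 5])


class TestDetectUptakeStart:
    def test_worked_example(self):
        # threshold = 1 + 0.05 * (9 - 1) = 1.4; first mean above it is at t=10
        s = series_from_means([1, 1, 5, 9, 9], [0, 5, 10, 15, 20])
        assert detect_uptake_start(s, full_mask()) == 10.0

    def test_monotone_increase_from_second_frame(self):
        s = series_from_means([0, 10, 20, 30], [0, 5, 10, 15])
        assert detect_uptake_start(s, full_mask()) == 5.0

    def test_constant_series_raises(self):
        s = series_from_means([3, 3, 3, 3], [0, 5, 10, 15])
        with pytest.raises(UptakeNotDetectedError):
            detect_uptake_start(s, full_mask())

    def test_too_few_frames(self):
        s = series_from_means([1, 2], [0, 5])
        with pytest.raises(ValueError):
            detect_uptake_start(s, full_mask())


class TestSumImage:
    def test_twelve_identical_frames(self):
        s = series_from_means([3.0] * 12, np.arange(12) * 5.0)
        out = sum_image(s, IntegrationWindow.all_frames())
        assert np.allclose(out.values, 36.0)

    def test_fixed_window_half_open(self):
        # frames at t=0..55 step 5; [10, 30) selects t in {10, 15, 20, 25}
        means = np.arange(12, dtype=float)
        s = series_from_means(means, np.arange(12) * 5.0)
        out = sum_image(s, IntegrationWindow.fixed(start_s=10, duration_s=20))
        assert np.allclose(out.values, 2 + 3 + 4 + 5)

    def test_last_minutes_tail(self):
        # 60-min series sampled each minute; last 20 min keeps t >= 40 min
        times = np.arange(61) * 60.0
        s = series_from_means(np.ones(61), times, shape=(2, 2, 2))
        out = sum_image(s, IntegrationWindow.last_minutes(20.0))
        assert np.allclose(out.values, 21.0)  # t = 40..60 min inclusive

    def test_empty_window_raises(self):
        s = series_from_means([1, 2, 3], [0, 5, 10])
        with pytest.raises(ValueError):
            sum_image(s, IntegrationWindow.fixed(start_s=100, duration_s=10))

    def test_additive_over_disjoint_windows(self, rng):
        data = rng.random((3, 3, 3, 10))
        s = DynamicSeries(data, np.arange(10) * 5.0, VOXEL)
        left = sum_image(s, IntegrationWindow.fixed(0, 25)).values
        right = sum_image(s, IntegrationWindow.fixed(25, 25)).values
        total = sum_image(s, IntegrationWindow.all_frames()).values
        np.testing.assert_allclose(left + right, total, rtol=1e-12)


class TestNormalizeGlobalMean:
    def test_two_voxel_example(self):
        values = np.zeros((3, 1, 1))
        values[:2, 0, 0] = [2.0, 4.0]
        mask = np.zeros((3, 1, 1), dtype=bool)
        mask[:2, 0, 0] = True
        out = normalize_global_mean(VolumeMap(values, VOXEL), mask)
        np.testing.assert_allclose(out.values[:2, 0, 0], [2 / 3, 4 / 3])
        assert out.values[2, 0, 0] == 0.0

    def test_mean_is_one(self, rng, mask):
        vmap = VolumeMap(rng.random(mask.shape) + 0.5, VOXEL)
        out = normalize_global_mean(vmap, mask)
        assert abs(out.values[mask].mean() - 1.0) < 1e-10

    def test_idempotent(self, rng, mask):
        vmap = VolumeMap(rng.random(mask.shape) + 0.5, VOXEL)
        once = normalize_global_mean(vmap, mask)
        twice = normalize_global_mean(once, mask)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        mask = np.ones((4, 4, 4), dtype=bool)
        base = rng.random((4, 4, 4)) + 0.1
        a = normalize_global_mean(VolumeMap(base, VOXEL), mask)
        b = normalize_global_mean(VolumeMap(base * scale, VOXEL), mask)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_nonpositive_mean_raises(self, mask):
        with pytest.raises(ValueError):
            normalize_global_mean(VolumeMap(np.zeros(mask.shape), VOXEL), mask)


class TestGroupMedian:
    def test_odd_count(self):
        maps = [VolumeMap(np.full((2, 2, 2), v), VOXEL) for v in (1.0, 2.0, 100.0)]
        assert np.allclose(group_median(maps).values, 2.0)

    def test_even_count_mid_mean(self):
        maps = [VolumeMap(np.full((2, 2, 2), v), VOXEL) for v in (1.0, 3.0)]
        assert np.allclose(group_median(maps).values, 2.0)

    def test_single_map_identity(self, rng):
        m = VolumeMap(rng.random((3, 3, 3)), VOXEL)
        np.testing.assert_array_equal(group_median([m]).values, m.values)

    def test_permutation_invariant(self, rng):
        maps = [VolumeMap(rng.random((3, 3, 3)), VOXEL) for _ in range(5)]
        ref = group_median(maps).values
        shuffled = [maps[i] for i in [3, 0, 4, 1, 2]]
        np.testing.assert_array_equal(group_median(shuffled).values, ref)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            group_median(
                [VolumeMap(np.zeros((2, 2, 2)), VOXEL), VolumeMap(np.zeros((3, 3, 3)), VOXEL)]
            )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            group_median([])

    def test_matches_sorting_oracle(self, rng):
        stack = rng.random((6, 2, 2, 2))
        maps = [VolumeMap(s, VOXEL) for s in stack]
        result = group_median(maps).values
        for idx in np.ndindex(2, 2, 2):
            vals = np.sort(stack[(slice(None),) + idx])
            expected = (vals[2] + vals[3]) / 2  # mid-mean of 6 sorted values
            assert result[idx] == pytest.approx(expected, abs=1e-15)


class TestGaussianSmooth:
    def test_sigma_conversion(self):
        # 14 mm FWHM on 6 mm voxels
        assert fwhm_to_sigma_vox(14.0, 6.0) == pytest.approx(0.990875, abs=1e-5)

    def test_constant_preserved(self, mask):
        vmap = VolumeMap(np.full(mask.shape, 7.0), VOXEL)
        out = gaussian_smooth(vmap, 14.0, mask)
        np.testing.assert_allclose(out.values[mask], 7.0, rtol=1e-12)

    def test_fwhm_zero_identity(self, rng, mask):
        vmap = VolumeMap(rng.random(mask.shape), VOXEL)
        out = gaussian_smooth(vmap, 0.0, mask)
        np.testing.assert_array_equal(out.values, vmap.values)

    def test_negative_fwhm_raises(self, mask):
        with pytest.raises(ValueError):
            gaussian_smooth(VolumeMap(np.zeros(mask.shape), VOXEL), -1.0, mask)

    def test_mean_shift_below_one_percent(self, latents, mask):
        vmap = latents[0].with_values(latents[0].values + 3.0)
        before = vmap.values[mask].mean()
        after = gaussian_smooth(vmap, 14.0, mask).values[mask].mean()
        assert abs(after - before) / abs(before) < 0.01


class TestOptimizeFwhm:
    def test_recovers_planted_scale(self, rng, mask):
        # a = 10 mm-smoothed field plus small noise; smoothing b at 10 mm
        # reproduces it best among the candidates
        fields = [rng.standard_normal(mask.shape) for _ in range(3)]
        maps_b = [VolumeMap(gaussian_smooth(VolumeMap(f, VOXEL), 12.0, mask).values, VOXEL)
                  for f in fields]
        maps_a = []
        for b in maps_b:
            smoothed = gaussian_smooth(b, 10.0, mask).values
            noise = 0.01 * rng.standard_normal(mask.shape) * smoothed[mask].std()
            maps_a.append(VolumeMap(smoothed + noise, VOXEL))
        best = optimize_fwhm(maps_a, maps_b, mask, [0.0, 5.0, 10.0, 20.0])
        assert best == 10.0

    def test_identical_lists_pick_zero(self, rng, mask):
        maps = [VolumeMap(rng.standard_normal(mask.shape), VOXEL) for _ in range(2)]
        assert optimize_fwhm(maps, maps, mask, [0.0, 5.0]) == 0.0

    def test_single_candidate(self, rng, mask):
        maps = [VolumeMap(rng.standard_normal(mask.shape), VOXEL)]
        assert optimize_fwhm(maps, maps, mask, [7.0]) == 7.0

    def test_empty_inputs_raise(self, mask):
        with pytest.raises(ValueError):
            optimize_fwhm([], [], mask, [5.0])
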