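import numpy as np
import pytest

from sfci.fc import (ConnectivityMap, correlation_map, extract_fc,
                     inplane_gaussian_filter, inplane_hamming_filter,
                     lowpass_filter, normalize_t_to_z, r_to_t, seed_reference)
from sfci.volumes import SeedROI, TimeSeriesVolume, VoxelGrid

AFFINE = np.diag([2.0, 2.0, 4.0, 1.0])
TR = 2.8


def _series(data):
    return TimeSeriesVolume(np.asarray(data, float), AFFINE, tr_s=TR)


def _mask(shape, fill=1):
    return VoxelGrid(np.full(shape, fill, dtype=np.uint8), AFFINE, units="binary")


def _sinusoid_series(freq_hz, n=200, shape=(4, 4, 2)):
    t = np.arange(n) * TR
    wave = np.sin(2 * np.pi * freq_hz * t)
    return _series(np.broadcast_to(wave, (*shape, n)).copy())


class TestLowpass:
    def test_stopband_sinusoid_strongly_attenuated(self):
        out = lowpass_filter(_sinusoid_series(0.15), cutoff_hz=0.08)
        ratio = out.values[0, 0, 0].std() / _sinusoid_series(0.15).values[0, 0, 0].std()
        assert ratio < 0.10

    def test_passband_sinusoid_preserved(self):
        out = lowpass_filter(_sinusoid_series(0.02), cutoff_hz=0.08)
        ratio = out.values[0, 0, 0].std() / _sinusoid_series(0.02).values[0, 0, 0].std()
        assert abs(ratio - 1.0) < 0.05

    def test_constant_series_unchanged(self):
        data = np.full((3, 3, 2, 50), 7.5)
        out = lowpass_filter(_series(data), cutoff_hz=0.08)
        np.testing.assert_allclose(out.values, data, atol=1e-10)

    def test_mean_preserved(self, rng):
        series = _series(rng.standard_normal((3, 3, 2, 60)) + 100.0)
        out = lowpass_filter(series, cutoff_hz=0.08)
        np.testing.assert_allclose(out.values.mean(axis=-1),
                                   series.values.mean(axis=-1), rtol=1e-9)

    def test_cutoff_at_or_above_nyquist_rejected(self, noise_series):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(noise_series, cutoff_hz=1.0 / (2 * TR))


class TestHamming:
    def test_spatially_constant_slice_unchanged(self):
        data = np.full((8, 8, 3, 5), 4.0)
        out = inplane_hamming_filter(_series(data))
        np.testing.assert_allclose(out.values, data, atol=1e-10)

    def test_impulse_sum_preserved(self):
        data = np.zeros((8, 8, 2, 3))
        data[4, 4, 0, :] = 1.0
        out = inplane_hamming_filter(_series(data))
        for t in range(3):
            assert out.values[:, :, 0, t].sum() == pytest.approx(1.0, abs=1e-9)
            # energy spread away from the impulse
            assert out.values[4, 4, 0, t] < 1.0

    def test_nyquist_stripes_attenuated_to_window_edge(self):
        # +1/-1 stripes along x sit at the in-plane Nyquist frequency
        stripes = np.cos(np.pi * np.arange(8))[:, None]
        data = np.broadcast_to(stripes[:, :, None, None], (8, 8, 2, 3)).copy()
        out = inplane_hamming_filter(_series(data))
        ratio = np.abs(out.values[:, :, 0, 0]).max() / 1.0
        assert ratio == pytest.approx(0.08, rel=1e-6)

    def test_too_small_inplane_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 4"):
            inplane_hamming_filter(_series(rng.standard_normal((3, 3, 2, 5))))


def test_gaussian_filter_smooths_and_keeps_constants(rng):
    series = _series(rng.standard_normal((12, 12, 2, 4)))
    out = inplane_gaussian_filter(series, fwhm_mm=4.0)
    assert out.values.var() < series.values.var()
    const = _series(np.full((12, 12, 2, 4), 3.25))
    np.testing.assert_allclose(inplane_gaussian_filter(const).values, 3.25, atol=1e-9)


class TestSeedReference:
    def test_identical_voxels_give_detrended_common_series(self, rng):
        s = rng.standard_normal(40)
        data = np.broadcast_to(s, (4, 4, 2, 40)).copy()
        seed = SeedROI(frozenset({(0, 0, 0), (1, 1, 1), (2, 3, 0)}), space="rsfmri")
        ref = seed_reference(_series(data), seed)
        t = np.arange(40.0)
        slope, intercept = np.polyfit(t, s, 1)
        np.testing.assert_allclose(ref.values, s - slope * t - intercept, atol=1e-12)

    def test_pure_ramp_detrends_to_zero(self):
        ramp = np.arange(30.0)
        data = np.broadcast_to(ramp, (3, 3, 2, 30)).copy()
        seed = SeedROI(frozenset({(1, 1, 1)}), space="rsfmri")
        ref = seed_reference(_series(data), seed)
        np.testing.assert_allclose(ref.values, 0.0, atol=1e-9)

    def test_matches_mean_then_detrend_oracle(self, rng):
        data = rng.standard_normal((5, 5, 3, 25))
        voxels = [(0, 1, 2), (1, 1, 1), (2, 4, 0), (4, 4, 2), (3, 0, 1)]
        seed = SeedROI(frozenset(voxels), space="rsfmri")
        ref = seed_reference(_series(data), seed)
        mean_ts = np.mean([data[v] for v in voxels], axis=0)
        t = np.arange(25.0)
        slope, intercept = np.polyfit(t, mean_ts, 1)
        np.testing.assert_allclose(ref.values, mean_ts - slope * t - intercept, atol=1e-12)

    def test_detrended_invariant_holds(self, rng):
        data = rng.standard_normal((4, 4, 2, 50)) + np.arange(50) * 0.3
        seed = SeedROI(frozenset({(0, 0, 0), (3, 3, 1)}), space="rsfmri")
        ref = seed_reference(_series(data), seed)
        t = np.arange(50.0)
        slope, intercept = np.polyfit(t, ref.values, 1)
        sd = ref.values.std()
        assert abs(slope) < 1e-9 * sd and abs(intercept) < 1e-9 * sd


class TestCorrelationMap:
    def test_self_and_anti_correlation(self, rng, noise_series):
        ref_vals = noise_series.values[2, 2, 1].copy()
        data = noise_series.values.copy()
        data[0, 0, 0] = ref_vals
        data[1, 0, 0] = -ref_vals
        series = _series(data)
        seed = SeedROI(frozenset({(2, 2, 1)}), space="rsfmri")
        ref = seed_reference(series, seed)
        # use the raw (undetrended-free) voxel: correlation with detrended ref
        cmap = correlation_map(series, ref, _mask(series.shape[:3]))
        # detrending the reference barely changes white noise; r close to +-1
        assert cmap.grid.values[0, 0, 0] > 0.99
        assert cmap.grid.values[1, 0, 0] < -0.99

    def test_matches_textbook_pearson(self, rng):
        data = rng.standard_normal((4, 3, 2, 30))
        series = _series(data)
        ref_values = rng.standard_normal(30)
        from sfci.fc import ReferenceTimeSeries
        ref = ReferenceTimeSeries(ref_values,
                                  SeedROI(frozenset({(0, 0, 0)}), space="rsfmri"))
        cmap = correlation_map(series, ref, _mask((4, 3, 2)))
        for idx in [(0, 0, 0), (1, 2, 1), (3, 1, 0)]:
            expected = np.corrcoef(data[idx], ref_values)[0, 1]
            assert cmap.grid.values[idx] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_ref_rejected(self, noise_series):
        from sfci.fc import ReferenceTimeSeries
        ref = ReferenceTimeSeries(np.zeros(noise_series.n_volumes),
                                  SeedROI(frozenset({(0, 0, 0)}), space="rsfmri"))
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_map(noise_series, ref, _mask(noise_series.shape[:3]))

    def test_zero_variance_voxel_flagged_r0(self, rng):
        data = rng.standard_normal((3, 3, 2, 20))
        data[2, 2, 1, :] = 5.0
        series = _series(data)
        from sfci.fc import ReferenceTimeSeries
        ref = ReferenceTimeSeries(rng.standard_normal(20),
                                  SeedROI(frozenset({(0, 0, 0)}), space="rsfmri"))
        cmap = correlation_map(series, ref, _mask((3, 3, 2)))
        assert cmap.grid.values[2, 2, 1] == 0.0
        assert cmap.invalid[2, 2, 1]


class TestRToT:
    def _rmap(self, values, mask=None):
        grid = VoxelGrid(np.asarray(values, float), AFFINE, units="r")
        return ConnectivityMap(grid=grid, stage="r", dof=100, mask=mask)

    def test_closed_form_at_n_132(self):
        r = np.full((2, 2, 2), 0.5)
        out = r_to_t(self._rmap(r), n_effective=132)
        expected = 0.5 * np.sqrt(130 / 0.75)
        assert expected == pytest.approx(6.583, abs=5e-4)
        np.testing.assert_allclose(out.grid.values, expected, rtol=1e-12)
        assert out.dof == 130

    def test_zero_and_odd_symmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, (3, 3, 2))
        r[0, 0, 0] = 0.0
        pos = r_to_t(self._rmap(r), 50).grid.values
        neg = r_to_t(self._rmap(-r), 50).grid.values
        assert pos[0, 0, 0] == 0.0
        np.testing.assert_allclose(pos, -neg, atol=1e-12)

    def test_unit_r_capped(self):
        r = np.zeros((2, 2, 1))
        r[0, 0, 0], r[1, 1, 0] = 1.0, -1.0
        out = r_to_t(self._rmap(r), 50, t_cap=1e6)
        assert out.grid.values[0, 0, 0] == 1e6
        assert out.grid.values[1, 1, 0] == -1e6

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n_effective"):
            r_to_t(self._rmap(np.zeros((2, 2, 1))), 2)


class TestNormalizeZ:
    def _tmap(self, values, mask):
        grid = VoxelGrid(np.asarray(values, float), AFFINE, units="t")
        return ConnectivityMap(grid=grid, stage="t", dof=100, mask=mask)

    def test_output_mean_zero_sd_one(self, rng):
        t = rng.standard_normal((6, 6, 3)) * 3 + 1
        mask = _mask((6, 6, 3))
        z = normalize_t_to_z(self._tmap(t, mask), mask)
        vals = z.grid.values[mask.values > 0]
        assert abs(vals.mean()) < 1e-9
        assert abs(vals.std() - 1.0) < 1e-9

    def test_affine_invariance(self, rng):
        t = rng.standard_normal((4, 4, 2))
        mask = _mask((4, 4, 2))
        z1 = normalize_t_to_z(self._tmap(t, mask), mask).grid.values
        z2 = normalize_t_to_z(self._tmap(3.7 * t - 11.0, mask), mask).grid.values
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_five_value_toy_map_population_sd(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0]).reshape(5, 1, 1)
        mask = _mask((5, 1, 1))
        z = normalize_t_to_z(self._tmap(t, mask), mask).grid.values.ravel()
        s2 = np.sqrt(2.0)
        np.testing.assert_allclose(z, [-s2, -s2 / 2, 0.0, s2 / 2, s2], atol=1e-12)

    def test_degenerate_map_rejected(self):
        mask = _mask((3, 3, 1))
        with pytest.raises(ValueError, match="degenerate"):
            normalize_t_to_z(self._tmap(np.full((3, 3, 1), 2.0), mask), mask)


class TestExtractFc:
    def _zmap(self, values, mask):
        grid = VoxelGrid(np.asarray(values, float), AFFINE, units="z")
        return ConnectivityMap(grid=grid, stage="z", dof=100, mask=mask)

    def test_constant_target(self):
        z = np.zeros((4, 4, 2))
        target_vox = {(0, 0, 0), (1, 1, 1), (2, 2, 0)}
        for v in target_vox:
            z[v] = 1.2
        target = SeedROI(frozenset(target_vox), space="rsfmri", role="target")
        fc = extract_fc(self._zmap(z, _mask((4, 4, 2))), target)
        assert fc.value == pytest.approx(1.2, abs=1e-12)

    def test_whole_mask_target_is_near_zero(self, rng):
        t = rng.standard_normal((4, 4, 2))
        mask = _mask((4, 4, 2))
        from sfci.fc import normalize_t_to_z
        z = normalize_t_to_z(ConnectivityMap(
            grid=VoxelGrid(t, AFFINE, "t"), stage="t", dof=50, mask=mask), mask)
        all_vox = {(i, j, k) for i in range(4) for j in range(4) for k in range(2)}
        target = SeedROI(frozenset(all_vox), space="rsfmri", role="target")
        assert extract_fc(z, target).value == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_mean(self, rng):
        z = rng.standard_normal((5, 5, 3))
        voxels = [(0, 0, 0), (1, 2, 1), (2, 2, 2), (4, 4, 0), (3, 1, 1),
                  (0, 4, 2), (2, 0, 0), (4, 0, 1), (1, 4, 2)]
        target = SeedROI(frozenset(voxels), space="rsfmri", role="target")
        fc = extract_fc(self._zmap(z, _mask((5, 5, 3))), target)
        assert fc.value == pytest.approx(np.mean([z[v] for v in voxels]), abs=1e-12)

    def test_target_outside_mask_rejected(self, rng):
        z = rng.standard_normal((4, 4, 2))
        mask = np.ones((4, 4, 2), dtype=np.uint8)
        mask[3, 3, 1] = 0
        target = SeedROI(frozenset({(3, 3, 1)}), space="rsfmri", role="target")
        with pytest.raises(ValueError, match="outside"):
            extract_fc(self._zmap(z, VoxelGrid(mask, AFFINE, "binary")), target)


class TestPipelineProperties:
    def test_deterministic_given_fixed_input(self):
        from sfci.fc import compute_fc
        from sfci.synthetic import make_image_fixtures
        fx = make_image_fixtures(shape=(16, 16, 6), rng_seed=5)
        v1 = compute_fc(fx.rest_series, fx.seed, fx.target, fx.brain_mask)
        v2 = compute_fc(fx.rest_series, fx.seed, fx.target, fx.brain_mask)
        assert v1.value == v2.value

    def test_fc_decreases_with_target_noise(self):
        # target = ref + sigma*noise: fc should fall monotonically in sigma
        from sfci.fc import compute_fc
        sigmas = [0.0, 0.5, 1.0, 2.0, 4.0]
        mean_fc = np.zeros(len(sigmas))
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            signal = r.standard_normal(60)
            base = r.standard_normal((14, 14, 4, 60))
            seed_roi = SeedROI(frozenset({(3 + dx, 7 + dy, 2) for dx in (-1, 0, 1)
                                          for dy in (-1, 0, 1)}), space="rsfmri")
            target_roi = SeedROI(frozenset({(10 + dx, 7 + dy, 2) for dx in (-1, 0, 1)
                                            for dy in (-1, 0, 1)}), space="rsfmri",
                                 role="target")
            for si, sigma in enumerate(sigmas):
                data = base.copy()
                for v in seed_roi.voxel_indices:
                    data[v] += 2 * signal
                for v in target_roi.voxel_indices:
                    data[v] += 2 * (signal + sigma * r.standard_normal(60))
                fc = compute_fc(_series(data), seed_roi, target_roi,
                                _mask((14, 14, 4)))
                mean_fc[si] += fc.value / n_seeds
        assert all(mean_fc[i] > mean_fc[i + 1] for i in range(len(sigmas) - 1))

    def test_independent_noise_fc_is_small(self):
        # fc is a mean of 9 unit-variance z values; without spatial smoothing
        # the target voxels are independent, so 3 standard errors = 3/sqrt(9)
        from sfci.fc import compute_fc
        n_sim, hits = 100, 0
        bound = 3.0 / np.sqrt(9)
        seed_roi = SeedROI(frozenset({(2 + dx, 5 + dy, 1) for dx in (-1, 0, 1)
                                      for dy in (-1, 0, 1)}), space="rsfmri")
        target_roi = SeedROI(frozenset({(8 + dx, 5 + dy, 1) for dx in (-1, 0, 1)
                                        for dy in (-1, 0, 1)}), space="rsfmri",
                             role="target")
        for seed in range(n_sim):
            r = np.random.default_rng(1000 + seed)
            data = r.standard_normal((12, 12, 3, 40))
            fc = compute_fc(_series(data), seed_roi, target_roi, _mask((12, 12, 3)),
                            spatial_filter=False)
            hits += abs(fc.value) < bound
        assert hits / n_sim >= 0.95
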