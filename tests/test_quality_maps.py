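import numpy as np
import pytest
from scipy import stats

from epiqc.data_io import VolumeSeries
from epiqc.quality_maps import (
    FWHM_TO_SIGMA,
    corr_brain,
    detrend_poly,
    gcor,
    grayplot,
    radial_correlate,
    seed_corr,
    tsnr_map,
    tsnr_volreg,
)


def pearson(a, b):
    return stats.pearsonr(a, b)[0]


class TestDetrendPoly:
    def test_order0_removes_constants(self):
        rows = np.full((3, 15), 42.0)
        np.testing.assert_allclose(detrend_poly(rows, 0), 0.0, atol=1e-12)

    def test_order1_removes_ramp(self):
        rows = np.outer([1.0, -2.0], np.arange(20.0)) + 5.0
        np.testing.assert_allclose(detrend_poly(rows, 1), 0.0, atol=1e-9)

    def test_residuals_orthogonal_to_basis(self, rng):
        from numpy.polynomial import legendre

        rows = rng.normal(size=(4, 30))
        resid = detrend_poly(rows, 3, run_lengths=[15, 15])
        for sl in (slice(0, 15), slice(15, 30)):
            basis = legendre.legvander(np.linspace(-1, 1, 15), 3)
            np.testing.assert_allclose(resid[:, sl] @ basis, 0.0, atol=1e-8)

    def test_per_run_independent_fits(self, rng):
        rows = rng.normal(size=(2, 24))
        joint = detrend_poly(rows, 1, run_lengths=[12, 12])
        left = detrend_poly(rows[:, :12], 1)
        np.testing.assert_allclose(joint[:, :12], left, atol=1e-10)

    def test_short_run_rejected(self):
        with pytest.raises(ValueError):
            detrend_poly(np.zeros((2, 6)), 2, run_lengths=[3, 3])


class TestTSNR:
    def test_direct_formula(self):
        sig = VolumeSeries(np.full((2, 2, 1, 10), 100.0))
        rng = np.random.default_rng(0)
        noise_rows = rng.normal(size=(4, 10))
        noise_rows *= 0.5 / noise_rows.std(axis=1, ddof=1, keepdims=True)
        noise = VolumeSeries(noise_rows.reshape(2, 2, 1, 10))
        out = tsnr_map(sig, noise, np.ones((2, 2, 1), bool))
        np.testing.assert_allclose(out.data, 200.0)

    def test_zero_variance_voxel_counted(self):
        sig = VolumeSeries(np.full((2, 1, 1, 8), 10.0))
        noise_data = np.zeros((2, 1, 1, 8))
        noise_data[0, 0, 0] = np.sin(np.arange(8))
        out = tsnr_map(sig, VolumeSeries(noise_data), np.ones((2, 1, 1), bool))
        assert out.extras["n_zero_sd"] == 1
        assert out.data[1, 0, 0] == 0.0

    def test_recovers_injected_noise_sd(self, rng):
        mean, sd = 500.0, 4.0
        data = mean + rng.normal(0, sd, size=(8, 8, 4, 120))
        vol = VolumeSeries(data)
        out = tsnr_volreg(vol, np.ones((8, 8, 4), bool), detrend_order=2)
        masked_mean = out.data.mean()
        assert masked_mean == pytest.approx(mean / sd, rel=0.05)

    def test_too_short_rejected(self):
        v = VolumeSeries(np.zeros((2, 2, 2, 1)))
        with pytest.raises(ValueError):
            tsnr_map(v, v, np.ones((2, 2, 2), bool))


class TestGcor:
    def test_identical_series_give_one(self, rng):
        s = rng.normal(size=20)
        data = np.tile(s, (3, 3, 2, 1))
        assert gcor(VolumeSeries(data), np.ones((3, 3, 2), bool)) == pytest.approx(1.0)

    def test_antisymmetric_halves_give_zero(self, rng):
        s = rng.normal(size=20)
        data = np.empty((2, 1, 1, 20))
        data[0, 0, 0] = s
        data[1, 0, 0] = -s
        assert gcor(VolumeSeries(data), np.ones((2, 1, 1), bool)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_brute_force_pairwise_mean(self, rng):
        data = rng.normal(size=(50, 1, 1, 30))
        vol = VolumeSeries(data)
        got = gcor(vol, np.ones((50, 1, 1), bool))
        corr = np.corrcoef(data[:, 0, 0, :])
        want = corr.mean()  # includes the diagonal of ones
        assert got == pytest.approx(want, abs=1e-10)

    def test_range_and_small_mask_error(self, rng):
        data = rng.normal(size=(4, 4, 2, 25))
        g = gcor(VolumeSeries(data), np.ones((4, 4, 2), bool))
        assert 0.0 <= g <= 1.0
        mask = np.zeros((4, 4, 2), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError):
            gcor(VolumeSeries(data), mask)


class TestCorrBrain:
    def test_everything_equal_to_global_mean(self, rng):
        s = rng.normal(size=25)
        data = np.tile(s, (3, 2, 2, 1))
        out = corr_brain(VolumeSeries(data), np.ones((3, 2, 2), bool))
        np.testing.assert_allclose(out.data, 1.0, atol=1e-10)

    def test_anticorrelated_voxel(self, rng):
        s = rng.normal(size=25)
        data = np.tile(s, (5, 1, 1, 1))
        data[4, 0, 0] = -s * 3.0  # still exactly anti-proportional to gmean?
        vol = VolumeSeries(data)
        out = corr_brain(vol, np.ones((5, 1, 1), bool))
        # voxel 4's series is -3s; the global mean is (4s - 3s)/5 = 0.2 s
        assert out.data[4, 0, 0] == pytest.approx(-1.0, abs=1e-10)

    def test_matches_per_voxel_oracle(self, rng):
        data = rng.normal(size=(4, 3, 2, 30))
        mask = rng.random((4, 3, 2)) > 0.25
        out = corr_brain(VolumeSeries(data), mask)
        gmean = data[mask].mean(axis=0)
        for idx in np.argwhere(mask):
            want = pearson(data[tuple(idx)], gmean)
            assert out.data[tuple(idx)] == pytest.approx(want, abs=1e-10)

    def test_display_defaults(self, rng):
        out = corr_brain(
            VolumeSeries(rng.normal(size=(3, 3, 2, 10))), np.ones((3, 3, 2), bool)
        )
        assert out.extras["display_thr"] == 0.3
        assert out.extras["display_range"] == 0.6


def dense_radial_oracle(vol, mask, fwhm_mm, truncate=3.0):
    """Direct-summation weighted-average correlation, separable kernel."""
    sig = [(fwhm_mm / FWHM_TO_SIGMA) / v for v in vol.voxdims]
    kernels = []
    for s in sig:
        radius = int(truncate * s + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / s) ** 2)
        kernels.append(k / k.sum())
    out = np.zeros(vol.shape3d)
    shape = vol.shape3d
    for i, j, k in np.argwhere(mask):
        wsum = 0.0
        acc = np.zeros(vol.n_t)
        for di, wi in zip(range(-len(kernels[0]) // 2 + 1, len(kernels[0]) // 2 + 1), kernels[0]):
            for dj, wj in zip(range(-len(kernels[1]) // 2 + 1, len(kernels[1]) // 2 + 1), kernels[1]):
                for dk, wk in zip(range(-len(kernels[2]) // 2 + 1, len(kernels[2]) // 2 + 1), kernels[2]):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                        continue
                    if not mask[ii, jj, kk]:
                        continue
                    w = wi * wj * wk
                    acc += w * vol.data[ii, jj, kk]
                    wsum += w
        out[i, j, k] = pearson(vol.data[i, j, k], acc / wsum)
    return out


class TestRadialCorrelate:
    def test_uniform_signal_gives_one(self, rng):
        s = rng.normal(size=15)
        data = np.tile(s, (5, 5, 3, 1))
        vol = VolumeSeries(data, voxdims=(3.0, 3.0, 3.0))
        out = radial_correlate(vol, np.ones((5, 5, 3), bool))
        np.testing.assert_allclose(out.data, 1.0, atol=1e-8)

    def test_single_voxel_mask_self_correlation(self, rng):
        data = rng.normal(size=(4, 4, 4, 12))
        mask = np.zeros((4, 4, 4), bool)
        mask[2, 2, 2] = True
        out = radial_correlate(VolumeSeries(data), mask)
        assert out.data[2, 2, 2] == pytest.approx(1.0)

    def test_matches_dense_oracle(self, rng):
        data = 100 + rng.normal(size=(16, 16, 16, 10))
        mask = rng.random((16, 16, 16)) > 0.4
        vol = VolumeSeries(data, voxdims=(3.0, 3.0, 3.0))
        got = radial_correlate(vol, mask, fwhm_mm=12.0)
        want = dense_radial_oracle(vol, mask, fwhm_mm=12.0)
        np.testing.assert_allclose(got.data[mask], want[mask], atol=1e-6)

    def test_huge_fwhm_approaches_corr_brain(self, rng):
        data = 10 + rng.normal(size=(8, 8, 6, 30))
        mask = np.ones((8, 8, 6), bool)
        vol = VolumeSeries(data, voxdims=(3.0, 3.0, 3.0))
        rad = radial_correlate(vol, mask, fwhm_mm=10 * 24.0)
        cb = corr_brain(vol, mask)
        np.testing.assert_allclose(rad.data[mask], cb.data[mask], atol=0.05)

    def test_invalid_fwhm(self, small_vol):
        vol, mask = small_vol
        with pytest.raises(ValueError):
            radial_correlate(vol, mask, fwhm_mm=0.0)

    def test_invariant_to_voxel_affine_rescale(self, rng):
        data = 100 + rng.normal(size=(6, 6, 4, 15))
        mask = np.ones((6, 6, 4), bool)
        vol = VolumeSeries(data, voxdims=(3.0, 3.0, 3.0))
        base = radial_correlate(vol, mask)
        data2 = data.copy()
        data2[2, 3, 1] = data2[2, 3, 1] * 5.0 + 40.0
        # correlation of *that voxel's* series with its neighborhood is
        # invariant to its own positive affine rescale only through the
        # correlation step; the neighborhood average changes for others,
        # so check just the rescaled voxel with neighbors excluded
        mask_single = np.zeros((6, 6, 4), bool)
        mask_single[2, 3, 1] = True
        a = radial_correlate(vol, mask_single)
        b = radial_correlate(VolumeSeries(data2, voxdims=(3.0, 3.0, 3.0)), mask_single)
        assert a.data[2, 3, 1] == pytest.approx(b.data[2, 3, 1], abs=1e-9)


class TestSeedCorr:
    def test_radius_zero_self_correlation(self, small_vol):
        vol, mask = small_vol
        seed = tuple(np.argwhere(mask)[0])
        out = seed_corr(vol, mask, seed, seed_radius_mm=0.0)
        assert out.data[seed] == pytest.approx(1.0)

    def test_planted_network_elevated(self, rng):
        data = 100 + rng.normal(0, 1.0, size=(8, 8, 4, 60))
        latent = rng.normal(size=60)
        network = np.zeros((8, 8, 4), bool)
        network[2:5, 2:5, 1:3] = True
        data[network] += 5.0 * latent
        mask = np.ones((8, 8, 4), bool)
        out = seed_corr(VolumeSeries(data), mask, (3, 3, 1), seed_radius_mm=0.0)
        assert out.data[network].min() > 0.8
        assert np.abs(out.data[~network]).mean() < 0.3

    def test_anticorrelated_region_negative(self, rng):
        data = 100 + rng.normal(0, 1.0, size=(8, 8, 4, 60))
        latent = rng.normal(size=60)
        pos = np.zeros((8, 8, 4), bool)
        pos[1:3, 1:3, :2] = True
        neg = np.zeros((8, 8, 4), bool)
        neg[5:7, 5:7, 2:] = True
        data[pos] += 5.0 * latent
        data[neg] -= 5.0 * latent
        out = seed_corr(VolumeSeries(data), np.ones((8, 8, 4), bool), (1, 1, 0))
        assert out.data[neg].max() < -0.8

    def test_seed_outside_grid_or_mask(self, small_vol):
        vol, mask = small_vol
        with pytest.raises(ValueError):
            seed_corr(vol, mask, (99, 0, 0))
        outside = tuple(np.argwhere(~mask)[0])
        with pytest.raises(ValueError):
            seed_corr(vol, mask, outside)


class TestGrayplot:
    def test_clip_value_is_two_sided_normal_tail(self, small_vol):
        vol, mask = small_vol
        gp = grayplot(vol, mask, clip_p=0.001)
        want = stats.norm.isf(0.0005)
        assert gp.clip == pytest.approx(want, abs=1e-4)
        assert gp.clip == pytest.approx(3.2905, abs=1e-4)
        assert np.max(np.abs(gp.values)) <= gp.clip + 1e-12

    def test_rank_one_data_all_rows_saturate_similarity(self, rng):
        s = rng.normal(size=50)
        weights = rng.uniform(0.5, 2.0, size=24)
        data = (weights[:, None] * s).reshape(4, 3, 2, 50) + 100.0
        vol = VolumeSeries(data)
        mask = np.ones((4, 3, 2), bool)
        gp = grayplot(vol, mask, detrend_order=0)
        # every row is proportional to one signal: identical after Z-scoring
        ref = gp.values[0]
        for row in gp.values:
            np.testing.assert_allclose(row, ref, atol=1e-8)

    def test_spatial_permutation_leaves_sorted_matrix_unchanged(self, rng):
        data = 100 + rng.normal(size=(4, 3, 2, 40))
        mask = np.ones((4, 3, 2), bool)
        vol = VolumeSeries(data)
        gp1 = grayplot(vol, mask)
        # swap contents of two voxels: same multiset of rows
        swapped = data.copy()
        swapped[0, 0, 0], swapped[3, 2, 1] = data[3, 2, 1].copy(), data[0, 0, 0].copy()
        gp2 = grayplot(VolumeSeries(swapped), mask)
        np.testing.assert_allclose(gp1.values, gp2.values, atol=1e-10)

    def test_zero_variance_rows_render_as_zero(self):
        data = np.zeros((2, 1, 1, 20))
        data[0, 0, 0] = np.sin(np.arange(20))
        gp = grayplot(VolumeSeries(data), np.ones((2, 1, 1), bool), detrend_order=0)
        assert np.all(gp.values[-1] == 0)
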