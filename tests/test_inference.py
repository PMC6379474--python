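import numpy as np
import pytest
from scipy import stats

from fcdens.inference import (
    alphasim_min_extent,
    estimate_smoothness,
    extract_clusters,
    fdr_threshold,
    min_extent_from_volume,
    one_sample_map,
    t_from_summary,
    two_sample_glm,
)
from fcdens.volumes import GrayMatterMask, VolumeGrid


class TestOneSample:
    def test_known_small_sample_value(self):
        # {1, 2, 3}: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.4641
        x = np.array([1.0, 2.0, 3.0])[:, None, None, None]
        t, p = one_sample_map(x)
        assert t[0, 0, 0] == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert p[0, 0, 0] == pytest.approx(
            2 * stats.t.sf(2 * np.sqrt(3), df=2), rel=1e-12)

    def test_zero_variance_voxel_is_nan(self):
        x = np.full((5, 2, 2, 2), 3.0)
        t, p = one_sample_map(x)
        assert np.all(np.isnan(t))

    def test_null_false_positive_rate_near_alpha(self, rng):
        x = rng.standard_normal((20, 2000))
        _, p = one_sample_map(x)
        rate = np.mean(p < 0.05)
        assert abs(rate - 0.05) < 0.02

    def test_mask_restricts_output(self, rng):
        x = rng.standard_normal((6, 4, 4, 4))
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = True
        t, p = one_sample_map(x, m)
        assert np.isfinite(t[0, 0, 0])
        assert np.isnan(t[1, 1, 1])


class TestFdr:
    def test_textbook_step_up_example(self):
        p = np.array([0.001, 0.02, 0.03, 0.9])
        rej = fdr_threshold(p, q=0.05)
        assert rej.tolist() == [True, True, True, False]

    def test_fdr_at_least_as_liberal_as_bonferroni(self, rng):
        p = rng.uniform(size=500) ** 3  # enriched small p values
        q = 0.05
        bonf = p < q / p.size
        bh = fdr_threshold(p, q=q)
        assert np.all(bh[bonf])

    def test_nan_never_significant(self):
        p = np.array([1e-9, np.nan])
        rej = fdr_threshold(p, q=0.05)
        assert rej.tolist() == [True, False]


class TestTwoSampleGlm:
    def test_reduces_to_pooled_t_without_covariates(self, rng):
        a = rng.standard_normal((12, 30))
        b = rng.standard_normal((12, 30)) + 0.5
        maps = np.concatenate([a, b])
        labels = ["control"] * 12 + ["patient"] * 12
        t, df = two_sample_glm(maps, labels)
        assert df == 22
        ref = stats.ttest_ind(b, a, axis=0).statistic
        assert np.allclose(t, ref, atol=1e-10)

    def test_permutation_null_is_calibrated(self, rng):
        maps = rng.standard_normal((24, 500))
        labels = ["control"] * 12 + ["patient"] * 12
        t, df = two_sample_glm(
            maps, labels, covariates=rng.standard_normal((24, 2)))
        p = 2 * stats.t.sf(np.abs(t), df=df)
        assert abs(np.mean(p < 0.05) - 0.05) < 0.03

    def test_constant_covariate_dropped_not_fatal(self, rng):
        maps = rng.standard_normal((10, 5))
        labels = ["control"] * 5 + ["patient"] * 5
        t_a, df_a = two_sample_glm(maps, labels, covariates=np.ones((10, 1)))
        t_b, df_b = two_sample_glm(maps, labels)
        assert df_a == df_b
        assert np.allclose(t_a, t_b)

    def test_group_confounded_covariate_raises(self, rng):
        maps = rng.standard_normal((10, 5))
        labels = ["control"] * 5 + ["patient"] * 5
        g = np.array([0.0] * 5 + [1.0] * 5)
        with pytest.raises(ValueError, match="rank"):
            two_sample_glm(maps, labels, covariates=g[:, None])

    def test_sign_convention_patients_minus_controls(self, rng):
        a = rng.standard_normal((20, 1))
        maps = np.concatenate([a, a + 5.0])
        labels = ["control"] * 20 + ["patient"] * 20
        t, _ = two_sample_glm(maps, labels)
        assert t[0] > 0


class TestSummaryT:
    def test_matches_scipy_from_raw_data(self, rng):
        a = rng.standard_normal(24) * 5 + 20
        b = rng.standard_normal(24) * 1 + 3
        want = stats.ttest_ind(a, b).statistic
        got = t_from_summary(a.mean(), a.std(ddof=1), 24,
                             b.mean(), b.std(ddof=1), 24)
        assert got == pytest.approx(want, rel=1e-12)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary(1, 1, 1, 0, 1, 24)


def _cube_mask(n, voxel=3.0):
    g = VolumeGrid((n, n, n), (voxel, voxel, voxel))
    return GrayMatterMask(g, np.ones((n, n, n), bool))


class TestSmoothness:
    def test_white_noise_fwhm_near_1p18_voxels(self, rng):
        mask = _cube_mask(16)
        resid = rng.standard_normal((20, 16, 16, 16))
        fwhm = estimate_smoothness(resid, mask)
        # sqrt(2 ln 2) ~ 1.1774 voxel widths = 3.532 mm at 3 mm voxels
        want = np.sqrt(2 * np.log(2)) * 3.0
        assert np.all(np.abs(fwhm - want) / want < 0.2)

    def test_smoothed_noise_recovers_combined_width(self, rng):
        from scipy import ndimage
        mask = _cube_mask(24)
        sigma_vox = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        resid = np.stack([
            ndimage.gaussian_filter(rng.standard_normal((24, 24, 24)),
                                    sigma_vox, mode="wrap")
            for _ in range(12)
        ])
        fwhm = estimate_smoothness(resid, mask)
        # intrinsic white-noise width adds in quadrature with the kernel
        want = np.sqrt(6.0**2 + 2 * np.log(2) * 3.0**2)
        assert np.all(np.abs(fwhm - want) / want < 0.2)

    def test_constant_residual_raises(self):
        mask = _cube_mask(8)
        with pytest.raises(ValueError, match="constant"):
            estimate_smoothness(np.ones((3, 8, 8, 8)), mask)


class TestAlphaSim:
    def test_unsmoothed_extent_small(self):
        mask = _cube_mask(12)
        k, maxima = alphasim_min_extent(mask, 0.0, voxel_p=0.01,
                                        n_iterations=200, seed=0)
        assert 1 <= k <= 4
        assert len(maxima) == 200

    def test_extent_monotone_in_smoothness(self):
        mask = _cube_mask(12)
        k0, _ = alphasim_min_extent(mask, 0.0, n_iterations=200, seed=0)
        k6, _ = alphasim_min_extent(mask, 6.0, n_iterations=200, seed=0)
        assert k6 > k0

    def test_threshold_controls_family_wise_rate(self):
        # split the null into calibration and evaluation halves
        mask = _cube_mask(12)
        k, _ = alphasim_min_extent(mask, 4.0, n_iterations=300, seed=1)
        _, maxima = alphasim_min_extent(mask, 4.0, n_iterations=300, seed=2)
        fwe = np.mean(maxima >= k)
        assert fwe <= 0.12

    def test_few_iterations_warn(self):
        mask = _cube_mask(12)
        with pytest.warns(RuntimeWarning, match="few"):
            alphasim_min_extent(mask, 0.0, n_iterations=50, seed=0)


class TestClusterExtraction:
    def test_extent_criterion_1080mm3_is_40_voxels(self):
        assert min_extent_from_volume(1080.0, 3.0) == 40
        assert min_extent_from_volume(27.0, 3.0) == 1

    def test_single_block_recovered_with_peak(self):
        t = np.zeros((10, 10, 10))
        t[2:5, 2:5, 2:5] = 6.0
        t[3, 3, 3] = 9.0
        g = VolumeGrid((10, 10, 10), (3, 3, 3))
        clusters = extract_clusters(t, df=46, voxel_p=0.01,
                                    min_extent=10, grid=g)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.sign == "increase"
        assert c.extent_voxels == 27
        assert c.extent_mm3 == pytest.approx(27 * 27.0)
        assert c.peak_t == pytest.approx(9.0)
        assert c.peak_world_mm == tuple(g.voxel_to_world((3, 3, 3)))

    def test_min_extent_filters_small_clusters(self):
        t = np.zeros((10, 10, 10))
        t[1, 1, 1] = 8.0  # single voxel
        t[5:8, 5:8, 5:8] = 8.0  # 27 voxels
        clusters = extract_clusters(t, df=46, voxel_p=0.01, min_extent=10)
        assert len(clusters) == 1
        assert clusters[0].extent_voxels == 27

    def test_sign_flip_symmetry(self):
        t = np.zeros((8, 8, 8))
        t[2:5, 2:5, 2:5] = 7.0
        pos = extract_clusters(t, df=20, voxel_p=0.01, min_extent=5)
        neg = extract_clusters(-t, df=20, voxel_p=0.01, min_extent=5)
        assert pos[0].sign == "increase" and neg[0].sign == "decrease"
        assert pos[0].extent_voxels == neg[0].extent_voxels
        assert pos[0].peak_t == -neg[0].peak_t

    def test_corner_connectivity_joins_diagonal_voxels(self):
        t = np.zeros((6, 6, 6))
        t[1, 1, 1] = 8.0
        t[2, 2, 2] = 8.0
        corners = extract_clusters(t, df=20, voxel_p=0.01, min_extent=1,
                                   connectivity="corners")
        faces = extract_clusters(t, df=20, voxel_p=0.01, min_extent=1,
                                 connectivity="faces")
        assert len(corners) == 1
        assert len(faces) == 2

    def test_subthreshold_map_gives_no_clusters(self):
        t_crit = stats.t.isf(0.005, df=46)
        t = np.full((5, 5, 5), t_crit - 0.01)
        assert extract_clusters(t, df=46, voxel_p=0.01, min_extent=1) == []
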