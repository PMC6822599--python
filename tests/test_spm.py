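import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from stepstab.spm import (estimate_fwhm, paired_t_scalar, rft_threshold,
                          rm_anova_2x2_scalar, rm_anova_oneway_scalar,
                          spm_paired_t, spm_rm_anova_2x2)


def smooth_gaussian_curves(rng, n, q, fwhm):
    sd = fwhm / 2.3548
    x = rng.normal(size=(n, q + 80))
    x = gaussian_filter1d(x, sd, axis=1, mode="wrap")[:, 40:40 + q]
    return x / x.std()


class TestPairedT:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = paired_t_scalar(a, a)
        assert t == 0.0 and df == 3 and p == 1.0

    def test_constant_nonzero_difference_flagged(self):
        a = np.array([2.0, 3.0, 4.0, 5.0])
        b = a - 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            t, _, p = paired_t_scalar(a, b)
        assert np.isinf(t) and np.isnan(p)

    def test_null_p_values_are_uniform(self, rng):
        ps = []
        for _ in range(2000):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            ps.append(paired_t_scalar(a, b)[2])
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.03

    def test_matches_scipy(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        t, _, p = paired_t_scalar(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestRmAnova2x2:
    def test_identical_cells_give_zero_f(self, rng):
        base = rng.normal(size=10)
        data = np.stack([np.stack([base, base], axis=1)] * 2, axis=1)
        table = rm_anova_2x2_scalar(data)
        for eff in table.effects.values():
            assert eff["F"] == pytest.approx(0.0, abs=1e-20)

    def test_f_equals_squared_contrast_t(self, rng):
        data = rng.normal(size=(12, 2, 2))
        table = rm_anova_2x2_scalar(data)
        inter = (data[:, 0, 0] - data[:, 1, 0]) - (data[:, 0, 1] - data[:, 1, 1])
        t = inter.mean() / (inter.std(ddof=1) / np.sqrt(len(inter)))
        assert table.effects["interaction"]["F"] == pytest.approx(t * t, abs=1e-10)
        cond = data[:, 0, :].mean(1) - data[:, 1, :].mean(1)
        t = cond.mean() / (cond.std(ddof=1) / np.sqrt(len(cond)))
        assert table.effects["condition"]["F"] == pytest.approx(t * t, abs=1e-10)

    def test_null_interaction_rejection_rate(self, rng):
        # additive effects, no interaction: rejections should track alpha
        hits = 0
        reps = 2000
        for _ in range(reps):
            subj = rng.normal(size=(8, 1, 1))
            a_eff = np.array([0.5, -0.5]).reshape(1, 2, 1)
            b_eff = np.array([0.2, -0.2]).reshape(1, 1, 2)
            data = subj + a_eff + b_eff + rng.normal(size=(8, 2, 2))
            table = rm_anova_2x2_scalar(data)
            hits += table.effects["interaction"]["p"] < 0.05
        assert abs(hits / reps - 0.05) < 0.02

    def test_missing_cells_rejected(self, rng):
        data = rng.normal(size=(6, 2, 2))
        data[2, 1, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2x2_scalar(data)

    def test_oneway_matches_two_level_paired_t(self, rng):
        data = rng.normal(size=(9, 2))
        res = rm_anova_oneway_scalar(data)
        t, _, p = paired_t_scalar(data[:, 0], data[:, 1])
        assert res["F"] == pytest.approx(t * t, abs=1e-10)
        assert res["p"] == pytest.approx(p, abs=1e-12)


class TestFwhm:
    def test_deterministic(self, rng):
        curves = smooth_gaussian_curves(rng, 8, 101, 8.0)
        assert estimate_fwhm(curves) == estimate_fwhm(curves.copy())

    def test_monotone_in_kernel_width(self, rng):
        vals = [estimate_fwhm(smooth_gaussian_curves(rng, 20, 101, f))
                for f in (3.0, 8.0, 16.0, 30.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_white_noise_is_rough(self, rng):
        r = rng.normal(size=(20, 101))
        assert estimate_fwhm(r - r.mean(0)) < 5.0

    def test_stability_across_seeds(self):
        vals = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            vals.append(estimate_fwhm(smooth_gaussian_curves(rng, 20, 101, 10.0)))
        assert np.std(vals) / np.mean(vals) < 0.2

    def test_constant_residuals_capped(self):
        with pytest.warns(UserWarning):
            v = estimate_fwhm(np.ones((4, 10)))
        assert v >= 1e5


class TestRftThreshold:
    def test_infinite_smoothness_limit(self):
        u = rft_threshold("t", df=9, fwhm=1e12, n_nodes=101, alpha=0.05)
        assert u == pytest.approx(stats.t.ppf(0.975, 9), abs=1e-6)

    def test_monotone_in_fwhm_and_nodes(self):
        u = [rft_threshold("t", 9, f, 101, 0.05) for f in (2, 5, 10, 50)]
        assert all(a > b for a, b in zip(u, u[1:]))
        u = [rft_threshold("t", 9, 10.0, n, 0.05) for n in (51, 101, 201)]
        assert all(a < b for a, b in zip(u, u[1:]))

    def test_f_threshold_is_squared_t_threshold(self):
        ut = rft_threshold("t", 9, 10.0, 101, 0.05)
        uf = rft_threshold("F", (1, 9), 10.0, 101, 0.05)
        assert uf == pytest.approx(ut * ut, rel=1e-10)

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            rft_threshold("t", 9, 10.0, 101, alpha=1.2)


class TestSpmPairedT:
    def test_identical_matrices_no_clusters(self, rng):
        A = smooth_gaussian_curves(rng, 10, 101, 10.0)
        res = spm_paired_t(A, A.copy(), method="permutation")
        np.testing.assert_allclose(res.stat_curve, 0.0)
        assert res.clusters == []

    def test_permutation_exhaustive_for_small_n(self, rng):
        A = smooth_gaussian_curves(rng, 6, 51, 8.0)
        B = smooth_gaussian_curves(rng, 6, 51, 8.0)
        r1 = spm_paired_t(A, B, method="permutation", seed=1)
        r2 = spm_paired_t(A, B, method="permutation", seed=99)
        # 2^6 = 64 <= 4096 -> exhaustive, so the seed cannot matter
        assert r1.threshold == r2.threshold

    def test_participant_reordering_invariance(self, rng):
        A = smooth_gaussian_curves(rng, 9, 101, 10.0)
        B = smooth_gaussian_curves(rng, 9, 101, 10.0)
        perm = rng.permutation(9)
        r1 = spm_paired_t(A, B, method="rft")
        r2 = spm_paired_t(A[perm], B[perm], method="rft")
        np.testing.assert_allclose(r1.stat_curve, r2.stat_curve, atol=1e-10)
        assert r1.threshold == pytest.approx(r2.threshold, abs=1e-10)

    def test_large_effect_is_detected(self, rng):
        A = smooth_gaussian_curves(rng, 10, 101, 10.0) + 2.0
        B = smooth_gaussian_curves(rng, 10, 101, 10.0)
        for method in ("rft", "permutation"):
            res = spm_paired_t(A, B, method=method)
            assert res.clusters, method

    def test_rft_and_permutation_thresholds_agree(self, rng):
        ratios = []
        for _ in range(20):
            A = smooth_gaussian_curves(rng, 10, 101, 10.0)
            B = smooth_gaussian_curves(rng, 10, 101, 10.0)
            r = spm_paired_t(A, B, method="rft")
            p = spm_paired_t(A, B, method="permutation")
            ratios.append(r.threshold / p.threshold)
        assert abs(np.mean(ratios) - 1.0) < 0.10


class TestSpmAnova:
    def test_identical_cells_zero_curves(self, rng):
        base = smooth_gaussian_curves(rng, 8, 51, 8.0)
        data = np.stack([np.stack([base, base], axis=1)] * 2, axis=1)
        out = spm_rm_anova_2x2(data)
        for res in out.values():
            np.testing.assert_allclose(res.stat_curve, 0.0, atol=1e-18)
            assert res.clusters == []

    def test_f_curve_equals_squared_contrast_t(self, rng):
        data = rng.normal(size=(10, 2, 2, 31))
        data = data + gaussian_filter1d(rng.normal(size=(10, 2, 2, 31)), 4, axis=3)
        out = spm_rm_anova_2x2(data)
        c = (data[:, 0, 0] - data[:, 1, 0]) - (data[:, 0, 1] - data[:, 1, 1])
        tcurve = c.mean(0) / (c.std(0, ddof=1) / np.sqrt(10))
        np.testing.assert_allclose(out["interaction"].stat_curve, tcurve**2,
                                   atol=1e-10)

    def test_condition_effect_detected(self, rng):
        data = np.empty((10, 2, 2, 101))
        for i in range(2):
            for j in range(2):
                data[:, i, j] = smooth_gaussian_curves(rng, 10, 101, 10.0)
        data[:, 1] -= 2.0  # strong condition effect, no interaction
        out = spm_rm_anova_2x2(data)
        assert out["condition"].clusters
        assert not out["interaction"].clusters
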