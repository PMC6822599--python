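import numpy as np
import pytest

from stepstab.synthetic import (GeneratorParams, analytic_profiles, analytic_r2,
                                make_cohort, preset_params, simulate_trial)


class TestParamsValidation:
    def test_walking_requires_double_support(self):
        with pytest.raises(ValueError, match="duty_factor"):
            GeneratorParams(mode="walking", duty_factor=0.4)

    def test_running_requires_flight(self):
        with pytest.raises(ValueError, match="duty_factor"):
            GeneratorParams(mode="running", duty_factor=0.6)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="fp_noise_sd"):
            GeneratorParams(fp_noise_sd=-0.01)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError, match="n_steps"):
            GeneratorParams(n_steps=1)

    def test_negative_beta2_rejected(self):
        with pytest.raises(ValueError, match="beta2"):
            GeneratorParams(beta2_profile=-0.1)


class TestSimulateTrial:
    def test_same_seed_is_bit_identical(self):
        p = preset_params("walking", n_steps=20, seed=9)
        t1, g1 = simulate_trial(p)
        t2, g2 = simulate_trial(p)
        for name in t1.markers:
            np.testing.assert_array_equal(t1.markers[name], t2.markers[name])
        np.testing.assert_array_equal(t1.force["fz"], t2.force["fz"])
        np.testing.assert_array_equal(g1.true_r2, g2.true_r2)

    def test_walking_force_never_zero(self, walking_trial):
        _, trial, _ = walking_trial
        assert trial.force["fz"].min() > 100.0

    def test_running_has_flight_phases(self, running_trial):
        _, trial, _ = running_trial
        assert np.percentile(trial.force["fz"], 5) < 10.0

    def test_trunk_marker_mean_is_com(self, walking_trial):
        params, trial, truth = walking_trial
        mean_ml = np.mean([trial.markers[f"trunk_{i}"][:, 0]
                           for i in (1, 2, 3)], axis=0)
        # mean of three independent noises has sd marker_noise_sd/sqrt(3)
        tol = 6 * params.marker_noise_sd / np.sqrt(3)
        assert np.max(np.abs(mean_ml - truth.com_series_clean)) < tol

    def test_event_ordering_and_alternation(self, running_trial):
        _, _, truth = running_trial
        for side in ("left", "right"):
            hs = truth.event_times[side]["heel_strikes"]
            to = truth.event_times[side]["toe_offs"]
            assert np.all(np.diff(hs) > 0) and np.all(np.diff(to) > 0)
            # each stance: heel strike then toe off, before the next heel strike
            for h, t in zip(hs, to):
                assert h < t
        merged = sorted(
            [(t, s) for s in ("left", "right")
             for t in truth.event_times[s]["heel_strikes"]])
        sides = [s for _, s in merged]
        assert all(a != b for a, b in zip(sides, sides[1:]))

    def test_step_width_ground_truth(self, walking_trial):
        params, _, truth = walking_trial
        assert truth.true_step_width == pytest.approx(params.mean_step_width)
        expected_sd = np.hypot(params.com_noise_sd, params.fp_noise_sd)
        assert truth.true_step_width_sd == pytest.approx(expected_sd)


class TestAnalyticR2:
    def test_zero_placement_noise_gives_unity(self):
        p = preset_params("walking", fp_noise_sd=0.0, com_decouple_sd=0.0)
        r2 = analytic_r2(p)
        np.testing.assert_allclose(r2, 1.0, atol=1e-6)

    def test_no_coupling_gives_zero(self):
        p = preset_params("walking", beta1_profile=0.0, beta2_profile=0.0,
                          fp_noise_sd=0.005)
        np.testing.assert_allclose(analytic_r2(p), 0.0, atol=1e-12)

    def test_equal_signal_and_noise_variance_gives_half(self):
        # position-only law: C carries the whole signal, Var(C) = Var(eps)
        sigma = 0.01
        p = preset_params("walking", beta1_profile=1.0, beta2_profile=0.0,
                          com_noise_sd=sigma, com_free_sd=0.0,
                          com_decouple_sd=0.0, fp_noise_sd=sigma)
        r2 = analytic_r2(p)
        np.testing.assert_allclose(r2, 0.5, atol=1e-9)

    def test_law_window_value_matches_variance_ratio(self):
        for mode in ("walking", "running"):
            p = preset_params(mode)
            expected = p.com_noise_sd**2 / (p.com_noise_sd**2 + p.fp_noise_sd**2)
            r2 = analytic_r2(p)
            assert r2[-1] == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("mode", ["walking", "running"])
    def test_matches_large_sample_fit(self, mode):
        """Monte-Carlo oracle: a long simulated trial fitted by the pipeline
        reproduces the closed-form profiles."""
        from stepstab import AnalysisConfig, analyze_trial
        p = preset_params(mode, n_steps=2000, seed=31, marker_noise_sd=0.0)
        trial, truth = simulate_trial(p)
        res = analyze_trial(trial, AnalysisConfig())
        assert np.nanmax(np.abs(res.r2_avg - truth.true_r2)) < 0.02


class TestMakeCohort:
    def test_trial_inventory(self):
        cohort = make_cohort(10, n_steps=10, seed=1)
        assert len(cohort) == 10
        for member in cohort:
            assert len(member["trials"]) == 8  # 4 speeds x 2 conditions
            modes = {p.mode for p in member["trials"]}
            assert modes == {"walking", "running"}

    def test_zero_between_subject_sd_shares_profiles(self):
        cohort = make_cohort(3, n_steps=10, seed=2, between_subject_sd=0.0)
        ref = analytic_profiles(cohort[0]["trials"][0])
        for member in cohort[1:]:
            prof = analytic_profiles(member["trials"][0])
            np.testing.assert_allclose(prof[2], ref[2], atol=1e-12)

    def test_rejects_single_participant(self):
        with pytest.raises(ValueError):
            make_cohort(1)

    def test_stabilized_condition_shrinks_width_and_signal(self):
        normal = preset_params("walking", "normal")
        stab = preset_params("walking", "stabilized")
        assert stab.mean_step_width < normal.mean_step_width
        assert stab.com_noise_sd < normal.com_noise_sd
        assert analytic_r2(stab)[-1] < analytic_r2(normal)[-1]
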