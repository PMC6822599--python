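import numpy as np
import pytest

from stepstab import AnalysisConfig, detect_events, midstance_times, segment_steps
from stepstab.placement import (SwingEnsemble, average_r2_over_legs,
                                build_ensembles, fit_fp_regression,
                                percent_nonsignificant_beta2,
                                time_normalize_swing)
from stepstab.preprocessing import com_state
from stepstab.trial_io import TrialRecording


def _ensembles(trial, config):
    com = com_state(trial)
    events = midstance_times(detect_events(trial, config))
    steps = segment_steps(events)
    return build_ensembles(trial, com, events, steps, config)


def _random_ensemble(rng, n_steps=40, grid=11, r2=0.7):
    grid_arr = np.linspace(0, 100, grid)
    C = rng.normal(size=(n_steps, grid))
    V = rng.normal(size=(n_steps, grid))
    signal = 0.8 * C[:, -1] + 0.3 * V[:, -1]
    noise_sd = np.std(signal) * np.sqrt((1 - r2) / r2)
    FP = signal + rng.normal(0, noise_sd, n_steps)
    C -= C.mean(0)
    V -= V.mean(0)
    FP -= FP.mean()
    return SwingEnsemble(leg="right", grid=grid_arr, C=C, V=V, FP=FP)


class TestTimeNormalize:
    def test_constant_series(self):
        t = np.arange(100) / 100.0
        out = time_normalize_swing(t, np.full(100, 2.5), 0.1, 0.8,
                                   np.linspace(0, 100, 11))
        np.testing.assert_allclose(out, 2.5)

    def test_linear_series_hits_endpoints(self):
        t = np.arange(200) / 100.0
        series = 3.0 * t
        grid = np.linspace(0, 100, 101)
        out = time_normalize_swing(t, series, 0.40, 1.20, grid)
        np.testing.assert_allclose(out[0], 1.2, atol=1e-9)
        np.testing.assert_allclose(out[-1], 3.6, atol=1e-9)
        np.testing.assert_allclose(np.diff(out), np.diff(out)[0], atol=1e-9)

    def test_grid_refinement_consistency(self):
        t = np.arange(1000) / 1000.0
        series = np.sin(2 * np.pi * 3 * t)
        coarse = time_normalize_swing(t, series, 0.1, 0.9,
                                      np.linspace(0, 100, 101))
        fine = time_normalize_swing(t, series, 0.1, 0.9,
                                    np.linspace(0, 100, 1001))
        np.testing.assert_allclose(coarse, fine[::10], atol=5e-4)

    def test_swing_outside_range_rejected(self):
        t = np.arange(100) / 100.0
        with pytest.raises(ValueError, match="outside"):
            time_normalize_swing(t, t, 0.5, 1.5, np.linspace(0, 100, 5))


class TestBuildEnsembles:
    def test_columns_are_centered(self, walking_trial, config):
        _, trial, _ = walking_trial
        for ens in _ensembles(trial, config).values():
            np.testing.assert_allclose(ens.C.mean(0), 0, atol=1e-12)
            np.testing.assert_allclose(ens.V.mean(0), 0, atol=1e-12)
            assert abs(ens.FP.mean()) < 1e-12

    def test_invariant_to_lateral_shift(self, walking_trial, config):
        _, trial, _ = walking_trial
        markers = {k: v + np.array([0.1, 0, 0]) for k, v in trial.markers.items()}
        force = dict(trial.force)
        force["cop_x"] = trial.force["cop_x"] + 0.1
        shifted = TrialRecording(markers=markers, force=force, meta=trial.meta)
        base = _ensembles(trial, config)
        moved = _ensembles(shifted, config)
        for leg in ("left", "right"):
            np.testing.assert_allclose(moved[leg].FP, base[leg].FP, atol=1e-9)
            np.testing.assert_allclose(moved[leg].C, base[leg].C, atol=1e-9)

    def test_noiseless_placements_match_ground_truth(self, clean_walking_trial,
                                                     config):
        params, trial, truth = clean_walking_trial
        ens = _ensembles(trial, config)
        x, sides = truth.footfall_x, truth.footfall_sides
        mirrored = {1: [], -1: []}
        for k in range(1, len(x)):
            mirrored[sides[k]].append(sides[k] * (x[k] - x[k - 1]))
        for leg, sign in (("right", 1), ("left", -1)):
            got = np.sort(ens[leg].FP)
            # generator placements, centered, for the swings the pipeline kept
            all_fp = np.array(mirrored[sign])
            # match: every measured placement appears among the true ones
            for v in ens[leg].FP + np.mean(all_fp[1:-1]):
                assert np.min(np.abs(all_fp - v)) < 1e-3


class TestFitRegression:
    def test_exact_linear_dependence(self, rng):
        ens = _random_ensemble(rng)
        ens = SwingEnsemble(leg="right", grid=ens.grid, C=ens.C, V=ens.V,
                            FP=0.5 * ens.C[:, 3])
        fit = fit_fp_regression(ens)
        assert fit.beta1[3] == pytest.approx(0.5, abs=1e-10)
        assert fit.r2[3] == pytest.approx(1.0, abs=1e-10)
        assert fit.p_beta1[3] == 0.0

    def test_independent_placement_has_tiny_r2(self, rng):
        n = 5000
        C = rng.normal(size=(n, 3))
        V = rng.normal(size=(n, 3))
        FP = rng.normal(size=n)
        ens = SwingEnsemble(leg="right", grid=np.array([0.0, 50.0, 100.0]),
                            C=C - C.mean(0), V=V - V.mean(0), FP=FP - FP.mean())
        fit = fit_fp_regression(ens)
        assert np.all(fit.r2 < 0.01)

    def test_matches_normal_equations(self, rng):
        for _ in range(20):
            ens = _random_ensemble(rng, n_steps=int(rng.integers(20, 200)))
            fit = fit_fp_regression(ens)
            for i in range(ens.grid.size):
                X = np.column_stack([ens.C[:, i], ens.V[:, i]])
                beta = np.linalg.inv(X.T @ X) @ X.T @ ens.FP
                pred = X @ beta
                r2 = (pred @ pred) / (ens.FP @ ens.FP)
                assert abs(fit.beta1[i] - beta[0]) < 1e-8
                assert abs(fit.beta2[i] - beta[1]) < 1e-8
                assert abs(fit.r2[i] - r2) < 1e-8

    def test_r2_variance_ratio_equals_one_minus_sse(self, rng):
        ens = _random_ensemble(rng)
        fit = fit_fp_regression(ens)
        for i in range(ens.grid.size):
            X = np.column_stack([ens.C[:, i], ens.V[:, i]])
            b = np.array([fit.beta1[i], fit.beta2[i]])
            sse = np.sum((ens.FP - X @ b) ** 2)
            sst = np.sum(ens.FP**2)
            assert fit.r2[i] == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_unit_invariance_mm_vs_m(self, rng):
        ens = _random_ensemble(rng)
        scaled = SwingEnsemble(leg="right", grid=ens.grid, C=ens.C * 1000,
                               V=ens.V * 1000, FP=ens.FP * 1000)
        f1 = fit_fp_regression(ens)
        f2 = fit_fp_regression(scaled)
        np.testing.assert_allclose(f1.r2, f2.r2, atol=1e-10)
        np.testing.assert_allclose(f1.beta1, f2.beta1, atol=1e-10)
        np.testing.assert_allclose(f1.p_beta2, f2.p_beta2, atol=1e-10)

    def test_adding_velocity_regressor_never_hurts(self, rng):
        ens = _random_ensemble(rng, n_steps=60)
        fit = fit_fp_regression(ens)
        for i in range(ens.grid.size):
            c = ens.C[:, i:i + 1]
            b = np.linalg.lstsq(c, ens.FP, rcond=None)[0]
            r2_c = float((c @ b) @ (c @ b)) / float(ens.FP @ ens.FP)
            assert fit.r2[i] >= r2_c - 1e-12

    def test_too_few_steps_rejected(self, rng):
        ens = _random_ensemble(rng, n_steps=3)
        with pytest.raises(ValueError, match="4 steps"):
            fit_fp_regression(ens)


class TestAggregation:
    def test_percent_nonsignificant_arithmetic(self, rng):
        fits = [fit_fp_regression(_random_ensemble(rng)) for _ in range(10)]
        for f in fits:
            f.p_beta2[:] = 0.001
        for f in fits[:3]:
            f.p_beta2[5] = 0.5
        pct = percent_nonsignificant_beta2(fits, alpha=0.05)
        assert pct[5] == pytest.approx(30.0)
        assert pct[0] == 0.0
        for f in fits:
            f.p_beta2[:] = 0.9
        assert np.all(percent_nonsignificant_beta2(fits) == 100.0)

    def test_average_r2_over_legs(self, rng):
        f1 = fit_fp_regression(_random_ensemble(rng))
        f2 = fit_fp_regression(_random_ensemble(rng))
        f1.r2[:] = 0.4
        f2.r2[:] = 0.6
        np.testing.assert_allclose(average_r2_over_legs(f1, f2), 0.5)
        f1.r2[4] = np.nan
        assert np.isnan(average_r2_over_legs(f1, f2)[4])

    def test_empty_fit_collection_rejected(self):
        with pytest.raises(ValueError):
            percent_nonsignificant_beta2([])
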