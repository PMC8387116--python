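"""Trial-by-trial regression, CV model comparison, pupil control."""

import numpy as np
import pandas as pd
import pytest

import lateraldopa as ld
from lateraldopa import regression as reg


@pytest.fixture(scope="module")
def trials500(task, observer):
    return ld.generate_trials(task, observer, 500, seed=50)


class TestBuildDesign:
    def test_contra_ipsi_assignment(self):
        trials = pd.DataFrame(
            {
                "contrast": [0.25, 0.5, 0.0],
                "stimulus_side": ["R", "L", "none"],
                "reward_volume": [1.4, 0.0, 2.4],
            }
        )
        spec = reg.DesignSpec(("contra_contrast", "ipsi_contrast"), standardize=False)
        X, y, dropped = reg.build_design(trials, np.zeros(3), spec, hemisphere="L")
        # left hemisphere: right-side stimuli are contralateral
        np.testing.assert_allclose(X["contra_contrast"], [0.25, 0.0, 0.0])
        np.testing.assert_allclose(X["ipsi_contrast"], [0.0, 0.5, 0.0])
        assert dropped == []

    def test_constant_column_dropped_with_warning(self, caplog):
        trials = pd.DataFrame(
            {
                "contrast": [0.25, 0.5, 0.25, 0.5],
                "stimulus_side": ["R", "R", "L", "L"],
                "reward_volume": [1.4, 1.4, 1.4, 1.4],
            }
        )
        spec = reg.DesignSpec(("contra_contrast", "reward_value"))
        with caplog.at_level("WARNING"):
            X, _, dropped = reg.build_design(trials, np.zeros(4), spec, "L")
        assert dropped == ["reward_value"]
        assert "reward_value" in caplog.text

    def test_standardized_columns_are_zscored(self, trials500):
        spec = reg.DesignSpec(("contra_contrast", "ipsi_contrast", "reward_value"))
        X, _, _ = reg.build_design(trials500, np.zeros(len(trials500)), spec, "L")
        assert np.allclose(X.mean(), 0, atol=1e-10)
        assert np.allclose(X.std(), 1, atol=1e-10)


class TestFitOLS:
    def test_exact_linear_data(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(0, 0.5, 50)
        X = pd.DataFrame({"contra_contrast": c})
        y = 3.0 + 2.0 * c
        fit = reg.fit_ols(X, y)
        assert fit.intercept == pytest.approx(3.0, abs=1e-9)
        assert fit.slopes["contra_contrast"] == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(fit.residuals, 0, atol=1e-9)

    def test_matches_brute_force_normal_equations(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(15, 3)), columns=["contra_contrast", "ipsi_contrast", "reward_value"])
        y = rng.normal(size=15)
        fit = reg.fit_ols(X, y)
        A = np.column_stack([np.ones(15), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        for j, name in enumerate(X.columns):
            assert fit.slopes[name] == pytest.approx(beta[j + 1], abs=1e-8)

    def test_null_slopes_covered_by_3se(self, task, observer):
        hits = 0
        reps = 40
        for k in range(reps):
            trials = ld.generate_trials(task, observer, 400, seed=200 + k)
            y = np.random.default_rng(300 + k).normal(size=len(trials))
            spec = reg.DesignSpec(("contra_contrast", "ipsi_contrast", "reward_value"))
            X, yy, _ = reg.build_design(trials, y, spec, "L")
            fit = reg.fit_ols(X, yy)
            if all(abs(fit.slopes[n]) < 3 * fit.slope_se[n] for n in X.columns):
                hits += 1
        assert hits / reps >= 0.9  # nominal coverage of 3 SE is ~99.7% per slope

    def test_parameter_recovery_on_linear_truth(self, trials500):
        beta = {"contra_contrast": 2.0, "ipsi_contrast": 1.0, "reward_value": 0.5}
        y = ld.linear_response_truth(trials500, "L", beta, noise_sd=0.3, seed=1)
        spec = reg.DesignSpec(tuple(beta), standardize=False)
        X, yy, _ = reg.build_design(trials500, y, spec, "L")
        fit = reg.fit_ols(X, yy)
        for name, b in beta.items():
            assert abs(fit.slopes[name] - b) < 3 * fit.slope_se[name]

    def test_rank_deficiency_names_columns(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"contra_contrast": x, "ipsi_contrast": 2 * x})
        with pytest.raises(ValueError, match="contra_contrast"):
            reg.fit_ols(X, x)


class TestCVExplainedVariance:
    def test_noiseless_linear_truth_gives_ev_one(self, trials500):
        y = ld.linear_response_truth(trials500, "L", {"contra_contrast": 2.0})
        spec = reg.DesignSpec(("contra_contrast",), standardize=False)
        X, yy, _ = reg.build_design(trials500, y, spec, "L")
        res = reg.cv_explained_variance(X, yy, k=5, seed=0)
        assert res.explained_variance == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_gives_near_zero_ev(self, task, observer):
        trials = ld.generate_trials(task, observer, 1000, seed=60)
        y = np.random.default_rng(61).normal(size=1000)
        spec = reg.DesignSpec(("contra_contrast", "ipsi_contrast", "reward_value"))
        X, yy, _ = reg.build_design(trials, y, spec, "L")
        res = reg.cv_explained_variance(X, yy, k=5, seed=0)
        assert res.explained_variance <= 0.05

    def test_same_seed_same_folds_and_ev(self, trials500):
        y = ld.linear_response_truth(trials500, "L", {"contra_contrast": 1.0}, noise_sd=1.0, seed=2)
        spec = reg.DesignSpec(("contra_contrast",))
        X, yy, _ = reg.build_design(trials500, y, spec, "L")
        a = reg.cv_explained_variance(X, yy, k=5, seed=42)
        b = reg.cv_explained_variance(X, yy, k=5, seed=42)
        assert a.explained_variance == b.explained_variance
        assert a.fold_ev == b.fold_ev

    def test_standardization_does_not_change_ev(self, trials500):
        y = ld.linear_response_truth(
            trials500, "L", {"contra_contrast": 2.0, "reward_value": 0.5}, noise_sd=0.5, seed=3
        )
        evs = {}
        for std in (True, False):
            spec = reg.DesignSpec(("contra_contrast", "reward_value"), standardize=std)
            X, yy, _ = reg.build_design(trials500, y, spec, "L")
            evs[std] = reg.cv_explained_variance(X, yy, k=5, seed=7).explained_variance
        assert evs[True] == pytest.approx(evs[False], abs=1e-10)

    def test_folds_partition_all_trials(self):
        folds = reg._fold_indices(103, 5, seed=0)
        concat = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(concat, np.arange(103))


class TestCompareNested:
    def test_contra_only_truth_selects_c_model(self, trials500):
        y = ld.linear_response_truth(trials500, "L", {"contra_contrast": 2.0}, noise_sd=0.2, seed=4)
        table = reg.compare_nested(trials500, y, "L", k=5, seed=0)
        ev = table.set_index("model")["explained_variance"]
        assert ev["c"] >= ev["civ"] - 0.01

    def test_full_truth_needs_full_model(self, trials500):
        beta = {"contra_contrast": 2.0, "ipsi_contrast": 1.5, "reward_value": 0.8}
        y = ld.linear_response_truth(trials500, "L", beta, noise_sd=0.2, seed=5)
        table = reg.compare_nested(trials500, y, "L", k=5, seed=0)
        ev = table.set_index("model")["explained_variance"]
        assert all(ev["civ"] > ev[m] for m in ev.index if m != "civ")

    def test_aic_and_ev_rankings_agree_on_strong_truth(self, trials500):
        y = ld.linear_response_truth(trials500, "L", {"contra_contrast": 2.0}, noise_sd=0.05, seed=6)
        table = reg.compare_nested(trials500, y, "L", k=5, seed=0)
        by_ev = table.sort_values("explained_variance", ascending=False)["model"].iloc[0]
        by_aic = table.sort_values("aic")["model"].iloc[0]
        # both criteria must prefer a model containing the true regressor
        assert "c" in by_ev and "c" in by_aic

    def test_reports_all_seven_models(self, trials500):
        y = ld.linear_response_truth(trials500, "L", {"contra_contrast": 1.0}, noise_sd=0.5, seed=7)
        table = reg.compare_nested(trials500, y, "L", k=5, seed=0)
        assert sorted(table["model"]) == sorted(["civ", "ci", "cv", "iv", "c", "i", "v"])


class TestPupilProjection:
    def test_collinear_points_preserve_ordering(self):
        t = np.linspace(0, 1, 200)
        xy = np.column_stack([t, 2 * t])
        p = reg.pupil_projection(xy, frame_rate=200.0, smooth_window=0.01)
        assert np.all(np.diff(p) >= 0)

    def test_output_is_zscored(self):
        rng = np.random.default_rng(8)
        xy = rng.normal(size=(500, 2))
        p = reg.pupil_projection(xy, frame_rate=30.0)
        assert abs(p.mean()) < 1e-10
        assert abs(p.std() - 1) < 1e-10

    def test_projection_axis_matches_eigendecomposition(self):
        rng = np.random.default_rng(9)
        xy = rng.normal(size=(2000, 2)) @ np.array([[2.0, 0.3], [0.3, 0.5]])
        w = 31  # median filter window (frames)
        from scipy.ndimage import median_filter
        sm = np.column_stack([median_filter(xy[:, j], size=w, mode="nearest") for j in (0, 1)])
        cov = np.cov((sm - sm.mean(0)).T)
        evals = np.linalg.eigvalsh(cov)
        p = reg.pupil_projection(xy, frame_rate=30.0, smooth_window=31 / 30.0)
        # variance captured by the projection equals the max eigenvalue
        proj_var_unscaled = evals.max()
        assert proj_var_unscaled == pytest.approx(
            np.var((sm - sm.mean(0)) @ _principal_axis(cov), ddof=1), rel=1e-6
        )
        assert abs(p.std() - 1) < 1e-10


def _principal_axis(cov):
    evals, evecs = np.linalg.eigh(cov)
    return evecs[:, np.argmax(evals)]


class TestEyeControl:
    def test_uncoupled_pupil_has_null_slope_while_contrast_drives(self, task, observer):
        from lateraldopa.pipeline import process_session
        photo = ld.PhotometryConfig(profile="DMS", hemisphere="L", noise_sd=0.001, artifact_rate=0.0)
        s = ld.generate_session(task, observer, photo, 500, seed=70, pupil_coupling=0.0)
        trials = process_session(s)["trials"]
        ok = trials["resp_stim"].notna()
        p1 = reg.pupil_projection(s.pupil_xy, 30.0)
        pt = reg.pupil_by_trial(p1, 30.0, trials.loc[ok, "stimulus_time"].to_numpy())
        fit, pairs = reg.eye_control(trials[ok], trials.loc[ok, "resp_stim"].to_numpy(), pt, "L")
        assert abs(fit.slopes["pupil"]) < 3 * fit.slope_se["pupil"]
        assert fit.slopes["contra_contrast"] > 3 * fit.slope_se["contra_contrast"]
        assert len(pairs) == ok.sum()

    def test_pupil_driven_response_recovered(self, task, observer):
        trials = ld.generate_trials(task, observer, 800, seed=71)
        xy = ld.generate_pupil(trials, coupling=0.0, frame_rate=30.0, seed=72)
        p1 = reg.pupil_projection(xy, 30.0)
        pt = reg.pupil_by_trial(p1, 30.0, trials["stimulus_time"].to_numpy())
        y = 1.0 * pt + np.random.default_rng(73).normal(0, 0.1, len(pt))
        fit, _ = reg.eye_control(trials, y, pt, "L", standardize=False)
        assert abs(fit.slopes["pupil"] - 1.0) < 3 * fit.slope_se["pupil"]
        for name in ("contra_contrast", "ipsi_contrast"):
            assert abs(fit.slopes[name]) < 3 * fit.slope_se[name]

    def test_constant_pupil_dropped(self, trials500):
        y = np.random.default_rng(74).normal(size=len(trials500))
        fit, _ = reg.eye_control(trials500, y, np.zeros(len(trials500)), "L")
        assert "pupil" in fit.dropped
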