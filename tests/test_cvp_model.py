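import itertools

import numpy as np
import pandas as pd
import pytest

from jvpulse.cvp_model import (
    SingularDesignError,
    cross_validate,
    fit_metrics,
    fit_ols,
    linear_model_aic,
    load_model,
    posthoc_power,
    predict,
    predict_published,
    published_model,
    save_model,
    select_model,
    coefficient_table,
)
from jvpulse.published import COHORT_MEAN_FEATURES, COHORT_MEAN_CVP, PUBLISHED_COEFFICIENTS
from jvpulse.signal_core import SignalValidationError

PUBLISHED_INPUT_NAMES = list(PUBLISHED_COEFFICIENTS)


def random_frame(rng, n, names):
    return pd.DataFrame({name: rng.normal(size=n) for name in names})


def aic_brute_force(frame, y, subset):
    """AIC via an independent lstsq fit: n ln(RSS/n) + 2(k+1)."""
    Z = np.column_stack([np.ones(len(frame))] + [frame[p].to_numpy() for p in subset])
    beta, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    rss = float(np.sum((y - Z @ beta) ** 2))
    return len(y) * np.log(rss / len(y)) + 2 * (len(subset) + 1)


class TestFitOls:
    def test_exact_linear_response(self, rng):
        frame = random_frame(rng, 30, ["a", "b"])
        y = 4.0 + 2.5 * frame["a"].to_numpy()
        model = fit_ols(frame, y, ["a"])
        assert model.coefficients["a"] == pytest.approx(2.5, abs=1e-9)
        assert model.intercept == pytest.approx(4.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_intercept_only(self, rng):
        frame = random_frame(rng, 25, ["a"])
        y = rng.normal(5, 1, 25)
        model = fit_ols(frame, y, [])
        assert model.intercept == pytest.approx(np.mean(y))
        assert model.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        frame = random_frame(rng, 40, ["a", "b", "c"])
        y = rng.normal(size=40)
        model = fit_ols(frame, y, ["a", "b", "c"])
        Z = np.column_stack([np.ones(40), frame[["a", "b", "c"]].to_numpy()])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        for name, b in zip(["a", "b", "c"], beta[1:]):
            assert model.coefficients[name] == pytest.approx(b, abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        frame = random_frame(rng, 40, ["a", "b"])
        y = 1.0 + frame["a"].to_numpy() - 2 * frame["b"].to_numpy() + rng.normal(0, 0.5, 40)
        model = fit_ols(frame, y, ["a", "b"])
        res = sm.OLS(y, sm.add_constant(frame[["a", "b"]].to_numpy())).fit()
        assert model.intercept == pytest.approx(res.params[0], abs=1e-10)
        assert model.coefficients["a"] == pytest.approx(res.params[1], abs=1e-10)
        assert model.aic == pytest.approx(
            len(y) * np.log(np.sum(res.resid**2) / len(y)) + 2 * 3
        )

    def test_coefficients_reproduce_fitted_values(self, rng):
        frame = random_frame(rng, 30, ["a", "b"])
        y = rng.normal(size=30)
        model = fit_ols(frame, y, ["a", "b"])
        rebuilt = predict(model, frame)
        np.testing.assert_allclose(rebuilt, model.fitted_values, atol=1e-9)

    def test_collinear_design_rejected(self, rng):
        frame = random_frame(rng, 30, ["a"])
        frame["b"] = 2.0 * frame["a"]
        with pytest.raises(SingularDesignError, match="a.*b"):
            fit_ols(frame, rng.normal(size=30), ["a", "b"])

    def test_too_few_subjects_rejected(self, rng):
        frame = random_frame(rng, 3, ["a", "b"])
        with pytest.raises(SignalValidationError):
            fit_ols(frame, np.arange(3.0), ["a", "b"])


class TestSelectModel:
    def test_signal_plus_noise_candidate(self, rng):
        frame = random_frame(rng, 50, ["x1", "x2"])
        y = 3.0 * frame["x1"].to_numpy() + rng.normal(0, 1e-4, 50)
        model = select_model(frame, y, ["x1", "x2"])
        assert model.selected_predictors == ("x1",)

    def test_null_response_prefers_intercept_only(self, rng):
        # pure-noise response: adding the candidate costs 2 AIC for an
        # expected chi^2(1) gain, so the intercept-only model wins on average
        wins = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            frame = random_frame(r, 200, ["x1"])
            y = r.normal(size=200)
            if select_model(frame, y, ["x1"]).selected_predictors == ():
                wins += 1
        assert wins > 20

    @pytest.mark.parametrize("n_candidates", [4, 8, 10])
    def test_matches_brute_force_enumeration(self, rng, n_candidates):
        names = [f"v{i}" for i in range(n_candidates)]
        frame = random_frame(rng, 45, names)
        y = (
            2 * frame["v0"].to_numpy()
            - 1.5 * frame["v1"].to_numpy()
            + rng.normal(0, 1.0, 45)
        )
        model = select_model(frame, y, names)
        best = min(
            (
                subset
                for size in range(n_candidates + 1)
                for subset in itertools.combinations(names, size)
            ),
            key=lambda s: aic_brute_force(frame, y, s),
        )
        assert set(model.selected_predictors) == set(best)
        assert model.aic == pytest.approx(aic_brute_force(frame, y, best), abs=1e-8)

    def test_greedy_agrees_on_strong_signal(self, rng):
        names = [f"v{i}" for i in range(6)]
        frame = random_frame(rng, 60, names)
        y = 5 * frame["v2"].to_numpy() - 4 * frame["v4"].to_numpy() + rng.normal(0, 0.1, 60)
        exhaustive = select_model(frame, y, names, strategy="exhaustive")
        greedy = select_model(frame, y, names, strategy="greedy")
        assert set(greedy.selected_predictors) >= {"v2", "v4"}
        assert set(exhaustive.selected_predictors) >= {"v2", "v4"}

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(SignalValidationError):
            select_model(random_frame(rng, 10, ["a"]), np.arange(10.0), [])

    def test_subset_size_capped_at_n_minus_2(self, rng):
        names = [f"v{i}" for i in range(6)]
        frame = random_frame(rng, 7, names)  # n - 2 = 5 predictors max
        y = rng.normal(size=7)
        model = select_model(frame, y, names)
        assert len(model.selected_predictors) <= 5

    def test_nested_r_squared_monotone(self, rng):
        frame = random_frame(rng, 40, ["a", "b", "c"])
        y = frame["a"].to_numpy() + rng.normal(0, 1, 40)
        full = fit_ols(frame, y, ["a", "b", "c"])
        for sub in (["a"], ["a", "b"], ["b", "c"]):
            assert full.r_squared >= fit_ols(frame, y, sub).r_squared - 1e-12


class TestPublishedPrediction:
    def test_all_zero_features_return_intercept(self):
        zero = {name: 0.0 for name in PUBLISHED_INPUT_NAMES}
        assert predict_published(zero) == -10.014

    def test_cohort_mean_features_near_cohort_mean_cvp(self):
        pred = predict_published(COHORT_MEAN_FEATURES)
        assert pred == pytest.approx(6.016321, abs=1e-6)  # direct arithmetic
        assert abs(pred - COHORT_MEAN_CVP) < 0.05  # coefficient-rounding slack

    def test_linearity_in_inputs(self):
        base = {name: v for name, v in COHORT_MEAN_FEATURES.items()}
        doubled = {name: 2 * v for name, v in base.items()}
        p1 = predict_published(base) - (-10.014)
        p2 = predict_published(doubled) - (-10.014)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_missing_lag_rejected(self):
        incomplete = {name: 0.0 for name in PUBLISHED_INPUT_NAMES if name != "lag240"}
        with pytest.raises(SignalValidationError, match="lag240"):
            predict_published(incomplete)

    def test_equals_model_constructed_from_published_coefficients(self, rng):
        model = published_model()
        row = {name: rng.normal() for name in PUBLISHED_INPUT_NAMES}
        assert predict(model, row) == pytest.approx(predict_published(row), abs=1e-12)


class TestPredict:
    def test_at_predictor_means_returns_response_mean(self, rng):
        frame = random_frame(rng, 30, ["a", "b"])
        y = rng.normal(5, 2, 30)
        model = fit_ols(frame, y, ["a", "b"])
        at_means = {"a": frame["a"].mean(), "b": frame["b"].mean()}
        assert predict(model, at_means) == pytest.approx(np.mean(y), abs=1e-9)

    def test_zero_coefficient_model_returns_intercept(self):
        model = published_model()
        model.coefficients = {name: 0.0 for name in model.selected_predictors}
        row = {name: 123.0 for name in model.selected_predictors}
        assert predict(model, row) == model.intercept


class TestCrossValidate:
    def test_noiseless_linear_response(self, rng):
        frame = random_frame(rng, 30, ["a"])
        y = 1.0 + 2.0 * frame["a"].to_numpy()
        report = cross_validate(frame, y, ["a"], k=10, seed=1)
        assert report.mae_cv == pytest.approx(0.0, abs=1e-9)
        assert report.r_squared_cv == pytest.approx(1.0, abs=1e-9)

    def test_leave_one_out_boundary(self, rng):
        frame = random_frame(rng, 12, ["a"])
        y = 2 * frame["a"].to_numpy() + rng.normal(0, 0.5, 12)
        report = cross_validate(frame, y, ["a"], k=12, seed=3)
        assert report.predictions.shape == (12,)
        assert len(np.unique(report.fold_assignments)) == 12

    def test_seed_reproducibility(self, rng):
        frame = random_frame(rng, 30, ["a", "b"])
        y = rng.normal(size=30)
        r1 = cross_validate(frame, y, ["a"], k=5, seed=42)
        r2 = cross_validate(frame, y, ["a"], k=5, seed=42)
        assert r1.mae_cv == r2.mae_cv and r1.r_squared_cv == r2.r_squared_cv
        np.testing.assert_array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_fold_sizes_differ_by_at_most_one(self, rng):
        frame = random_frame(rng, 34, ["a"])
        report = cross_validate(frame, rng.normal(size=34), ["a"], k=10, seed=0)
        counts = np.bincount(report.fold_assignments)
        assert counts.max() - counts.min() <= 1

    def test_k_larger_than_n_rejected(self, rng):
        frame = random_frame(rng, 5, ["a"])
        with pytest.raises(SignalValidationError):
            cross_validate(frame, np.arange(5.0), ["a"], k=6, seed=0)

    def test_cv_error_exceeds_in_sample_on_average(self):
        gaps = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            frame = random_frame(r, 30, ["a", "b"])
            y = frame["a"].to_numpy() + r.normal(0, 1.0, 30)
            model = fit_ols(frame, y, ["a", "b"])
            cv = cross_validate(frame, y, ["a", "b"], k=10, seed=seed)
            gaps.append(cv.mae_cv - model.mae)
        assert np.mean(gaps) > 0


class TestFitMetrics:
    def test_perfect_prediction(self):
        assert fit_metrics([1, 2, 3], [1, 2, 3]) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_constant_offset(self):
        r2, mae = fit_metrics([1, 2, 3], [2, 3, 4])
        assert (r2, mae) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_hand_computed_triple(self):
        r2, mae = fit_metrics([1, 2, 3], [1, 3, 2])
        assert mae == pytest.approx(2 / 3)
        assert r2 == pytest.approx(0.25)

    def test_zero_variance_rejected(self):
        with pytest.raises(SignalValidationError):
            fit_metrics([1, 1, 1], [1, 2, 3])


class TestPosthocPower:
    def test_published_effect_size(self):
        report = posthoc_power(0.612, n=34, n_predictors=11)
        assert round(report.cohens_f2, 3) == 1.577
        assert report.power == pytest.approx(0.993, abs=2e-3)

    def test_symmetry_point(self):
        assert posthoc_power(0.5, 34, 5).cohens_f2 == pytest.approx(1.0)

    def test_null_effect(self):
        report = posthoc_power(0.0, 34, 5, alpha=0.05)
        assert report.cohens_f2 == 0.0
        assert report.power == pytest.approx(0.05)

    def test_perfect_fit_rejected(self):
        with pytest.raises(SignalValidationError):
            posthoc_power(1.0, 34, 5)


class TestSerializationAndReport:
    def test_round_trip(self, tmp_path, rng):
        frame = random_frame(rng, 30, ["a", "b"])
        y = rng.normal(size=30)
        model = fit_ols(frame, y, ["a", "b"])
        path = tmp_path / "model.tsv"
        save_model(model, path)
        back = load_model(path)
        assert back.selected_predictors == model.selected_predictors
        assert back.coefficients == model.coefficients
        assert back.intercept == model.intercept
        assert back.aic == model.aic

    def test_coefficient_table_layout(self, rng):
        frame = random_frame(rng, 30, ["a", "b"])
        y = frame["a"].to_numpy() + rng.normal(0, 0.3, 30)
        table = coefficient_table(frame, y, ["a", "b"])
        assert list(table["predictor"]) == ["intercept", "a", "b"]
        assert ((table["ci_low"] <= table["coefficient"]) & (table["coefficient"] <= table["ci_high"])).all()
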