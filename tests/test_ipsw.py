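import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from trialemu.ipsw import (
    SeparationError,
    att_weights,
    balance_report,
    design_matrix,
    effective_n,
    fit_logistic,
    predict_proba,
    smd,
    weighted_mean_sd,
)


class TestFitLogistic:
    def test_balanced_strata_give_zero_coefficients(self):
        # 2/4 positive in each stratum of a binary covariate: no association
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        y = np.array([1, 1, 0, 0, 1, 1, 0, 0], dtype=float)
        fit = fit_logistic(x, y)
        assert fit.converged
        assert abs(fit.coefficients["intercept"]) < 1e-8
        assert abs(fit.coefficients["x0"]) < 1e-8

    def test_agrees_with_statsmodels_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(60, 200))
            X = rng.normal(size=(n, 3))
            beta = rng.normal(size=3)
            eta = X @ beta
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.sum() < 5 or y.sum() > n - 5:
                continue
            fit = fit_logistic(X, y)
            oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton", tol=1e-12)
            assert fit.converged
            assert abs(fit.log_likelihood - oracle.llf) < 1e-8
            np.testing.assert_allclose(fit.coef_vector, oracle.params, atol=1e-6)

    def test_null_slopes_with_independent_labels(self):
        rng = np.random.default_rng(2)
        n = 4000
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_logistic(X, y)
        # asymptotic SE of a logistic slope with p~0.4: 1/sqrt(n p (1-p))
        se = 1 / np.sqrt(n * 0.4 * 0.6)
        for name in fit.feature_names:
            assert abs(fit.coefficients[name]) < 2.5 * se

    def test_separation_flagged_and_weights_refused(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
        y = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        fit = fit_logistic(x, y)
        assert not fit.converged
        rows = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(4)],
                "laterality": ["OD"] * 4,
                "age": [70] * 4,
                "gender": ["F"] * 4,
                "baseline_letters": [60] * 4,
            }
        )
        with pytest.raises(SeparationError):
            att_weights(fit, rows)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((4, 1)), np.array([0, 1, 0, 1]))  # constant col
        with pytest.raises(ValueError):
            fit_logistic(np.arange(4.0), np.array([1, 1, 1, 1]))  # one class
        with pytest.raises(ValueError):
            fit_logistic(np.arange(4.0), np.array([0, 1, 2, 1]))  # not binary


def _frame(ages, genders, letters):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(ages))],
            "laterality": ["OD"] * len(ages),
            "age": ages,
            "gender": genders,
            "baseline_letters": letters,
        }
    )


class TestAttWeights:
    def test_identical_distributions_give_unit_weights(self):
        rng = np.random.default_rng(3)
        ages = rng.integers(60, 90, size=40)
        letters = rng.integers(40, 80, size=40)
        genders = np.where(rng.random(40) < 0.5, "F", "M")
        trial = _frame(ages, genders, letters)
        registry = _frame(ages, genders, letters)
        X = np.vstack([design_matrix(trial), design_matrix(registry)])
        y = np.concatenate([np.ones(40), np.zeros(40)])
        fit = fit_logistic(X, y)
        ws = att_weights(fit, registry)
        np.testing.assert_allclose(ws.weights, 1.0, atol=1e-6)

    def test_two_stratum_closed_form(self):
        # trial 30/10 across strata, registry 10/30: odds ratio 3 vs 1/3.
        # Hand-computable: p(stratum A) = 30/40, p(B) = 10/40, so raw odds
        # are 3 and 1/3; rescaled to sum 40 they stay exactly 3 and 1/3.
        x = np.concatenate([np.ones(30), np.zeros(10), np.ones(10), np.zeros(30)])
        y = np.concatenate([np.ones(40), np.zeros(40)])
        fit = fit_logistic(x, y)
        registry = _frame(
            ages=np.full(40, 70),
            genders=np.concatenate([["F"] * 10, ["M"] * 30]),
            letters=np.full(40, 60),
        )
        p = predict_proba(fit, x[40:])
        raw = p / (1 - p)
        weights = raw * 40 / raw.sum()
        np.testing.assert_allclose(weights[:10], 3.0, atol=1e-6)
        np.testing.assert_allclose(weights[10:], 1 / 3, atol=1e-6)
        assert abs(weights.sum() - 40) < 1e-9

    def test_weights_positive_and_sum_to_n(self, trial_df, clean_cohorts):
        from trialemu.pipeline import weight_trial_arm

        cohort_df = clean_cohorts[2]
        _, ws, _ = weight_trial_arm(trial_df, cohort_df, "ranibizumab_monthly")
        assert (ws.weights > 0).all()
        assert abs(ws.weights.sum() - ws.n_target) < 1e-9 * ws.n_target


class TestWeightedStats:
    def test_uniform_weights_match_ordinary(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        mean, sd = weighted_mean_sd(x, np.ones(50))
        assert mean == pytest.approx(float(np.mean(x)), abs=1e-12)
        assert sd == pytest.approx(float(np.std(x, ddof=1)), abs=1e-12)

    def test_three_point_example(self):
        mean, _ = weighted_mean_sd([1.0, 3.0], [1.0, 2.0])
        assert mean == pytest.approx(7 / 3)

    def test_dominant_weight_limit(self):
        mean, _ = weighted_mean_sd([5.0, 100.0], [1e-9, 10.0])
        assert mean == pytest.approx(100.0, abs=1e-6)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_sd([1.0, 2.0], [1.0, 0.0])

    def test_effective_n(self):
        assert effective_n(np.ones(7)) == pytest.approx(7.0)
        assert effective_n([1.0, 1.0, 2.0]) == pytest.approx(16 / 6)
        assert effective_n([100.0, 1e-6]) == pytest.approx(1.0, abs=1e-4)
        with pytest.raises(ValueError):
            effective_n([])

    def test_smd_examples(self):
        assert smd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)
        a = np.array([0.0, 1.0, 2.0]) + 1
        b = np.array([0.0, 1.0, 2.0])
        assert smd(a, b) == pytest.approx(1.0)
        assert np.isnan(smd([1.0, 1.0], [1.0, 1.0]))


class TestBalance:
    def test_weighting_reduces_smd_on_shifted_arm(self, trial_df):
        from trialemu.cohort import cohorts_frame, run_attrition
        from trialemu.pipeline import weight_trial_arm
        from trialemu.synthetic import SimConfig, generate_registry

        cfg = SimConfig(n_patients=500, seed=17, age_mean=84.0, baseline_letters_mean=55.0)
        registry, _ = generate_registry(cfg)
        cohorts, _ = run_attrition(registry)
        cohort_df = cohorts_frame(cohorts)
        _, ws, report = weight_trial_arm(trial_df, cohort_df, "bevacizumab_monthly")
        before = report["smd_before"].abs()
        after = report["smd_after"].abs()
        assert (after <= before + 1e-9).all()
        assert after.max() < 0.15
        assert report.attrs["effective_n"] <= ws.n_target
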