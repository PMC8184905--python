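"""Evaluation statistics against independent direct-formula oracles and the
protocol's worked examples."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from datprog.evaluation import (
    DegenerateInputError,
    PredictionSet,
    bias_test,
    bland_altman,
    diff_squared_errors,
    error_metrics,
    evaluate_predictions,
    failure_cases,
    ols_with_bands,
    pearson,
    shapiro_wilk,
    t_mean_ci,
)


def _pset(obs, pred, ids=None):
    return PredictionSet(np.asarray(obs, float), np.asarray(pred, float), ids)


class TestErrorMetrics:
    def test_two_case_worked_example(self):
        em = error_metrics(_pset([10, 20], [11, 18]))
        assert em.mape.estimate == pytest.approx(10.0)
        assert em.mae.estimate == pytest.approx(1.5)
        assert em.mse.estimate == pytest.approx(2.5)

    def test_perfect_prediction(self):
        em = error_metrics(_pset([5, 10, 15], [5, 10, 15]))
        assert em.mape.estimate == 0 and em.mae.estimate == 0 and em.mse.estimate == 0

    def test_zero_observed_undefines_mape_only(self):
        em = error_metrics(_pset([0, 10, 20], [1, 9, 21]))
        assert em.mape is None and em.mape_undefined_reason
        assert em.mae.estimate == pytest.approx(1.0)

    def test_ci_midpoint_equals_estimate(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(5, 2, rng.integers(3, 50))
            ci = t_mean_ci(x)
            assert 0.5 * (ci.ci_low + ci.ci_high) == pytest.approx(ci.estimate, abs=1e-12)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_mape_invariant_to_common_rescaling(self, scale):
        obs = np.array([10.0, 20.0, 30.0, 15.0])
        pred = np.array([12.0, 17.0, 33.0, 15.5])
        base = error_metrics(_pset(obs, pred)).mape.estimate
        scaled = error_metrics(_pset(scale * obs, scale * pred)).mape.estimate
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_mse_at_least_mae_squared(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            obs = rng.uniform(5, 50, 20)
            pred = obs + rng.normal(0, 5, 20)
            em = error_metrics(_pset(obs, pred))
            assert em.mse.estimate >= em.mae.estimate**2 - 1e-12


class TestPearson:
    def test_identity_and_antilinearity(self):
        obs = np.array([3.0, 7.0, 11.0, 20.0])
        assert pearson(_pset(obs, obs))[0] == pytest.approx(1.0)
        assert pearson(_pset(obs, -obs + 5))[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        r, _ = pearson(_pset(obs, pred))
        num = np.mean((obs - obs.mean()) * (pred - pred.mean()))
        expected = num / (obs.std() * pred.std())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson(_pset([1, 1, 1], [1, 2, 3]))


class TestOLSWithBands:
    def test_exact_linear_fit(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = ols_with_bands(_pset(obs, 2 * obs + 1))
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert np.all(fit.confidence_high - fit.confidence_low < 1e-8)

    def test_prediction_band_contains_confidence_band(self):
        rng = np.random.default_rng(2)
        obs = rng.uniform(10, 60, 30)
        pred = obs + rng.normal(0, 5, 30)
        fit = ols_with_bands(_pset(obs, pred))
        assert np.all(fit.prediction_low <= fit.confidence_low + 1e-12)
        assert np.all(fit.prediction_high >= fit.confidence_high - 1e-12)

    def test_matches_normal_equations(self):
        obs = np.array([12.0, 25.0, 31.0, 44.0, 52.0, 60.0])
        pred = np.array([15.0, 22.0, 35.0, 41.0, 55.0, 58.0])
        fit = ols_with_bands(_pset(obs, pred))
        A = np.vstack([np.ones_like(obs), obs]).T
        beta = np.linalg.solve(A.T @ A, A.T @ pred)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(DegenerateInputError):
            ols_with_bands(_pset([5, 5, 5], [1, 2, 3]))


class TestBlandAltman:
    def test_perfect_agreement_is_degenerate(self):
        rep = bland_altman(_pset([10, 20, 30], [10, 20, 30]))
        assert rep.degenerate
        assert rep.mean_difference.estimate == 0
        assert rep.loa_lower.estimate == rep.loa_upper.estimate == 0

    def test_symmetric_differences_against_two_pass_formula(self):
        d = np.tile([-1.0, 1.0], 50)
        obs = np.full(100, 30.0) + d
        rep = bland_altman(_pset(obs, np.full(100, 30.0)))
        sd = math.sqrt(sum((x - d.mean()) ** 2 for x in d) / (len(d) - 1))
        assert rep.mean_difference.estimate == pytest.approx(0.0, abs=1e-12)
        assert rep.loa_upper.estimate == pytest.approx(1.96 * sd, abs=1e-12)
        assert rep.loa_lower.estimate == pytest.approx(-1.96 * sd, abs=1e-12)

    def test_limits_midpoint_and_width_identities(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            obs = rng.uniform(10, 60, 25)
            pred = obs + rng.normal(1, 4, 25)
            rep = bland_altman(_pset(obs, pred))
            mid = 0.5 * (rep.loa_lower.estimate + rep.loa_upper.estimate)
            width = rep.loa_upper.estimate - rep.loa_lower.estimate
            assert mid == pytest.approx(rep.mean_difference.estimate, abs=1e-10)
            assert width == pytest.approx(2 * 1.96 * rep.sd_differences, abs=1e-10)

    def test_loa_confidence_interval_uses_bland_altman_se(self):
        rng = np.random.default_rng(4)
        obs = rng.uniform(10, 60, 40)
        pred = obs + rng.normal(0, 5, 40)
        rep = bland_altman(_pset(obs, pred))
        se = rep.sd_differences * math.sqrt(3.0 / 40)
        tq = stats.t.ppf(0.975, 39)
        assert rep.loa_upper.ci_high - rep.loa_upper.estimate == pytest.approx(tq * se, abs=1e-10)


class TestBiasTest:
    def test_exactly_centered_sample_has_p_one(self):
        assert bias_test(np.array([-2.0, -1.0, 0.0, 1.0, 2.0])) == pytest.approx(1.0)

    def test_clear_bias_detected(self):
        assert bias_test(np.array([5.0, 5.1, 4.9, 5.2, 4.8])) < 1e-3

    def test_constant_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            bias_test(np.array([2.0, 2.0, 2.0]))


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(5)
        pvals = [shapiro_wilk(rng.normal(0, 1, 40))[1] for _ in range(500)]
        assert np.mean(np.array(pvals) > 0.05) >= 0.90

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(6)
        _, p = shapiro_wilk(rng.exponential(1.0, 200))
        assert p < 0.01

    def test_statistic_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for n in (3, 10, 100):
            w, _ = shapiro_wilk(rng.normal(0, 1, n))
            assert 0 < w <= 1

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            shapiro_wilk(np.ones(10))


class TestFailureCases:
    def test_identical_mapes_flag_nothing(self):
        res = failure_cases(_pset([10, 10, 10], [9, 9, 9]))
        assert res.cases == []

    def test_threshold_arithmetic_no_flags(self):
        obs = np.full(5, 100.0)
        pred = obs - np.array([10, 10, 10, 10, 80])  # per-case MAPE 10,10,10,10,80
        res = failure_cases(_pset(obs, pred))
        m = np.array([10, 10, 10, 10, 80.0])
        assert res.threshold == pytest.approx(m.mean() + 2 * m.std(ddof=1))
        assert res.cases == []

    def test_extreme_case_flagged(self):
        obs = np.full(10, 100.0)
        errs = np.array([10.0] * 9 + [100.0])
        res = failure_cases(_pset(obs, obs - errs, [f"p{i}" for i in range(10)]))
        assert [c[0] for c in res.cases] == ["p9"]
        assert res.cases[0][1] == pytest.approx(100.0)


class TestDiffSquaredErrors:
    def test_identical_models_degenerate(self):
        y = np.array([10.0, 20.0, 30.0])
        res = diff_squared_errors(y + 1, y + 1, y)
        assert res.degenerate and res.mean.estimate == 0

    def test_perfect_model_sign_convention(self):
        y = np.array([10.0, 20.0, 30.0, 40.0])
        b = y + np.array([1.0, -2.0, 3.0, -1.0])
        res = diff_squared_errors(y, b, y)
        assert res.mean.estimate == pytest.approx(-np.mean((b - y) ** 2))
        assert res.mean.estimate <= 0

    def test_four_case_fixture_against_paired_t_oracle(self):
        y = np.array([20.0, 30.0, 40.0, 50.0])
        a = np.array([24.0, 27.0, 45.0, 48.0])
        b = np.array([21.0, 32.0, 38.0, 53.0])
        res = diff_squared_errors(a, b, y)
        delta = (a - y) ** 2 - (b - y) ** 2  # [7, -5, 21, -5]
        assert np.allclose(res.delta, delta)
        assert res.mean.estimate == pytest.approx(delta.mean())
        t_stat = delta.mean() / (delta.std(ddof=1) / math.sqrt(4))
        p_oracle = 2 * stats.t.sf(abs(t_stat), 3)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            diff_squared_errors(np.ones(3), np.ones(4), np.ones(4))


class TestFullReport:
    def test_report_serializes_with_all_fields(self, tmp_path):
        rng = np.random.default_rng(8)
        obs = rng.uniform(10, 60, 40)
        pred = obs + rng.normal(0, 5, 40)
        rep = evaluate_predictions(_pset(obs, pred))
        rep.to_json(tmp_path / "report.json")
        import json

        loaded = json.loads((tmp_path / "report.json").read_text())
        for key in ("mape", "mae", "mse", "pearson_r", "regression", "bland_altman", "failures"):
            assert key in loaded and loaded[key] is not None

    def test_csv_round_trip(self, tmp_path):
        p = _pset([10.0, 20.0, 30.0], [11.0, 19.0, 33.0], ["a", "b", "c"])
        p.to_csv(tmp_path / "pred.csv")
        q = PredictionSet.from_csv(tmp_path / "pred.csv")
        assert np.array_equal(p.observed, q.observed)
        assert np.array_equal(p.predicted, q.predicted)
        assert p.patient_ids == q.patient_ids
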