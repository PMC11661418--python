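"""KM, concordance, Brier, OE, smoothed calibration, calibration slope."""

import numpy as np
import pandas as pd
import pytest

import stratmatch as sm
from stratmatch.metrics import MetricError, censoring_km

from conftest import make_cohort


def naive_harrell(t, y, risk):
    """Independent pairwise enumeration with the pinned conventions."""
    conc = tied = usable = 0
    n = len(t)
    for i in range(n):
        if y[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            if t[j] > t[i] or (t[j] == t[i] and y[j] == 0):
                usable += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    tied += 1
    if usable == 0:
        raise ZeroDivisionError
    return (conc + 0.5 * tied) / usable


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        S = sm.km_estimator([1.0, 2.0, 3.0], [1, 1, 1])
        assert S(1.5) == pytest.approx(2 / 3)
        assert S(2.5) == pytest.approx(1 / 3)

    def test_all_censored_flat_one(self):
        S = sm.km_estimator([1.0, 2.0], [0, 0])
        assert S(10.0) == 1.0

    def test_single_event_among_two(self):
        S = sm.km_estimator([1.0, 2.0], [1, 0])
        assert S(1.0) == pytest.approx(0.5)

    def test_starts_at_one_nonincreasing(self):
        rng = np.random.default_rng(0)
        S = sm.km_estimator(rng.exponential(5, 100), rng.integers(0, 2, 100))
        grid = np.linspace(0, 30, 200)
        vals = S(grid)
        assert S(0.0) <= 1.0 and np.all(np.diff(vals) <= 1e-12)


class TestHarrellC:
    def test_perfect_concordance(self):
        assert sm.harrell_c([1, 2, 3], [1, 1, 1], [3, 2, 1]) == 1.0

    def test_three_pair_enumeration(self):
        assert sm.harrell_c([1, 2, 3], [1, 1, 1], [2, 3, 1]) == pytest.approx(2 / 3)

    def test_all_tied_risks_half(self):
        assert sm.harrell_c([1, 2, 3], [1, 1, 1], [5, 5, 5]) == 0.5

    def test_matches_naive_enumeration_with_ties_and_censoring(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = 15
            t = rng.integers(1, 6, n).astype(float)
            y = rng.integers(0, 2, n)
            risk = rng.integers(0, 4, n).astype(float)
            if y.sum() == 0:
                continue
            try:
                expected = naive_harrell(t, y, risk)
            except ZeroDivisionError:
                continue
            assert sm.harrell_c(t, y, risk) == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        t, y = rng.exponential(5, 80), rng.integers(0, 2, 80)
        y[0] = 1
        risk = rng.uniform(0, 1, 80)
        a = sm.harrell_c(t, y, risk)
        assert sm.harrell_c(t, y, np.exp(3 * risk)) == pytest.approx(a)
        assert sm.uno_c(t, y, np.exp(3 * risk), tau=10.0) == pytest.approx(
            sm.uno_c(t, y, risk, tau=10.0)
        )

    def test_reversal_identity_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 60)
        y = rng.integers(0, 2, 60)
        y[:3] = 1
        risk = rng.uniform(0, 1, 60)
        assert sm.harrell_c(t, y, risk) + sm.harrell_c(t, y, -risk) == pytest.approx(1.0)

    def test_no_events_undefined(self):
        with pytest.raises(MetricError):
            sm.harrell_c([1, 2], [0, 0], [1, 2])


class TestUnoC:
    def test_equals_harrell_without_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 100)
        y = np.ones(100, dtype=int)
        risk = rng.uniform(0, 1, 100)
        assert sm.uno_c(t, y, risk, tau=t.max() + 1) == pytest.approx(
            sm.harrell_c(t, y, risk)
        )

    def test_three_subject_enumeration(self):
        assert sm.uno_c([1, 2, 3], [1, 1, 1], [2, 3, 1], tau=4.0) == pytest.approx(2 / 3)

    def test_censoring_bias_correction_direction(self):
        """High-risk patients censored early: Harrell inflates concordance of a
        partially wrong score more than the IPCW-weighted Uno does."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 600
            x = rng.normal(size=n)
            T = rng.exponential(1 / (0.05 * np.exp(0.9 * x)))
            # censor high-risk subjects aggressively
            C = np.where(x > 0.5, rng.uniform(0, 8, n), rng.uniform(0, 80, n))
            t = np.minimum(T, C)
            y = (T <= C).astype(int)
            risk = 0.9 * x + rng.normal(scale=0.8, size=n)
            diffs.append(
                sm.harrell_c(t, y, risk) - sm.uno_c(t, y, risk, tau=40.0)
            )
        assert np.mean(diffs) != pytest.approx(0.0, abs=1e-4)


class TestBrier:
    def test_perfect_predictions_zero(self):
        t = np.array([1.0, 2.0, 10.0, 12.0])
        y = np.array([1, 1, 1, 1])
        risk = np.array([1.0, 1.0, 0.0, 0.0])
        assert sm.brier_score(t, y, risk, horizon=5.0) == 0.0

    def test_constant_half_risk_quarter(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 200)
        y = np.ones(200, dtype=int)
        assert sm.brier_score(t, y, np.full(200, 0.5), horizon=5.0) == pytest.approx(0.25)

    def test_no_censoring_equals_mse(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(5, 300)
        y = np.ones(300, dtype=int)
        risk = rng.uniform(0, 1, 300)
        h = 6.0
        mse = np.mean((risk - (t <= h)) ** 2)
        assert sm.brier_score(t, y, risk, h) == pytest.approx(mse)

    def test_matches_sksurv_graf_estimator(self):
        from sksurv.metrics import brier_score as sks_brier
        from sksurv.util import Surv

        rng = np.random.default_rng(7)
        t = rng.exponential(10, 400)
        c = rng.uniform(0, 25, 400)
        y = (t <= c).astype(int)
        tt = np.minimum(t, c)
        risk = rng.uniform(0, 1, 400)
        h = 8.0
        s = Surv.from_arrays(y.astype(bool), tt)
        _, (expected,) = sks_brier(s, s, (1 - risk)[:, None], [h])
        assert sm.brier_score(tt, y, risk, h) == pytest.approx(expected, rel=1e-6)

    def test_calibrated_risk_expectation(self):
        """With risk equal to the true event probability and no censoring,
        E[Brier] = E[risk (1 - risk)]."""
        rng = np.random.default_rng(8)
        n = 5000
        risk = rng.uniform(0.05, 0.95, n)
        event = rng.uniform(size=n) < risk
        t = np.where(event, 1.0, 100.0)
        score = sm.brier_score(t, np.ones(n, int), risk, horizon=50.0)
        assert score == pytest.approx(np.mean(risk * (1 - risk)), abs=0.01)


class TestOERatio:
    def test_no_censoring_event_fraction(self):
        t = np.array([1.0, 2, 3, 70, 80])
        y = np.ones(5, dtype=int)
        risk = np.full(5, 0.6)
        assert sm.oe_ratio(t, y, risk, horizon=60.0) == pytest.approx((3 / 5) / 0.6)

    def test_scaling(self):
        rng = np.random.default_rng(9)
        t, y = rng.exponential(40, 500), np.ones(500, int)
        risk = rng.uniform(0.2, 0.8, 500)
        r1 = sm.oe_ratio(t, y, risk, 60.0)
        assert sm.oe_ratio(t, y, risk / 2, 60.0) == pytest.approx(2 * r1)

    def test_near_one_when_calibrated(self):
        cohort, truth = sm.generate_cohort(
            sm.GeneratorConfig(n=5000, treatment_effect=0.0, confounding_scale=0.0, seed=12)
        )
        fit = sm.fit_cox(cohort)
        risk = fit.predict_risk(cohort, 60.0)
        assert sm.oe_ratio(cohort.t, cohort.y, risk, 60.0) == pytest.approx(1.0, abs=0.05)

    def test_zero_mean_risk_rejected(self):
        with pytest.raises(MetricError):
            sm.oe_ratio([1.0], [1], [0.0], 5.0)


class TestSmoothedCalibration:
    def test_degenerate_constant_risk_uses_km(self):
        rng = np.random.default_rng(10)
        n = 500
        event = rng.uniform(size=n) < 0.3
        t = np.where(event, 10.0, 100.0)
        obs = sm.smoothed_calibration(t, np.ones(n, int), np.full(n, 0.3), horizon=60.0)
        assert np.allclose(obs, obs[0])
        assert obs[0] == pytest.approx(0.3, abs=0.05)

    def test_calibrated_model_small_ici(self):
        cohort, _ = sm.generate_cohort(
            sm.GeneratorConfig(n=5000, treatment_effect=0.0, confounding_scale=0.0, seed=13)
        )
        fit = sm.fit_cox(cohort)
        risk = fit.predict_risk(cohort, 60.0)
        obs = sm.smoothed_calibration(cohort.t, cohort.y, risk, 60.0)
        assert np.mean(np.abs(obs - risk)) < 0.03

    def test_detects_injected_miscalibration(self):
        cohort, _ = sm.generate_cohort(
            sm.GeneratorConfig(n=4000, treatment_effect=0.0, confounding_scale=0.0, seed=14)
        )
        fit = sm.fit_cox(cohort)
        risk = fit.predict_risk(cohort, 60.0)
        obs_good = sm.smoothed_calibration(cohort.t, cohort.y, risk, 60.0)
        obs_bad = sm.smoothed_calibration(cohort.t, cohort.y, risk**2, 60.0)
        ici_good, *_ = sm.calibration_errors(obs_good, risk)
        ici_bad, *_ = sm.calibration_errors(obs_bad, risk**2)
        assert ici_bad > 3 * ici_good


class TestCalibrationErrors:
    def test_zero_when_observed_equals_predicted(self):
        r = np.linspace(0.1, 0.9, 20)
        assert sm.calibration_errors(r, r) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        obs = np.array([0.1, 0.1, 0.1, 0.5])
        ici, e50, e90, emax = sm.calibration_errors(obs, np.zeros(4))
        assert ici == pytest.approx(0.2)
        assert e50 == pytest.approx(0.1)
        assert emax == pytest.approx(0.5)

    def test_order_statistic_inequalities(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            obs, risk = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
            ici, e50, e90, emax = sm.calibration_errors(obs, risk)
            assert ici <= emax and e50 <= e90 <= emax

    def test_empty_rejected(self):
        with pytest.raises(MetricError):
            sm.calibration_errors([], [])


class TestCalibrationSlope:
    def test_training_data_slope_is_one(self, default_cohort):
        cohort, _ = default_cohort
        fit = sm.fit_cox(cohort, include_treatment=True)
        assert sm.calibration_slope(fit, cohort) == pytest.approx(1.0, abs=1e-6)

    def test_doubled_lp_halves_slope(self, default_cohort):
        cohort, _ = default_cohort
        fit = sm.fit_cox(cohort, include_treatment=True)

        class Doubled:
            includes_treatment = True

            def linear_predictor(self, c):
                return 2.0 * fit.linear_predictor(c)

        assert sm.calibration_slope(Doubled(), cohort) == pytest.approx(0.5, abs=1e-6)

    def test_overfit_model_shrinks_on_fresh_data(self):
        below = 0
        for seed in range(20):
            cfg = sm.GeneratorConfig(n=120, seed=300 + seed)
            train, _ = sm.generate_cohort(cfg)
            test, _ = sm.generate_cohort(
                sm.GeneratorConfig(n=2000, seed=9000 + seed)
            )
            fit = sm.fit_cox(train)
            below += sm.calibration_slope(fit, test) < 1.0
        assert below >= 16

    def test_constant_lp_rejected(self, default_cohort):
        cohort, _ = default_cohort

        class Flat:
            includes_treatment = False

            def linear_predictor(self, c):
                return np.zeros(c.n)

        with pytest.raises(MetricError):
            sm.calibration_slope(Flat(), cohort)


def test_censoring_km_is_survival_of_censoring_distribution():
    t = np.array([1.0, 2.0, 3.0])
    G = censoring_km(t, np.array([1, 0, 1]))  # single censoring at t=2
    assert G(1.9) == 1.0 and G(2.1) == pytest.approx(0.5)


def test_metrics_reproducible_given_fixed_inputs(default_cohort):
    cohort, _ = default_cohort
    fit = sm.fit_cox(cohort, include_treatment=True)
    m1 = sm.evaluate_model(fit, cohort, 60.0)
    m2 = sm.evaluate_model(fit, cohort, 60.0)
    assert m1 == m2
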