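"""Kaplan-Meier, log-rank and Cox partial-likelihood tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from predictval.survival import (CoxConvergenceError, breslow_cumulative_hazard,
                                 breslow_hazard_at, cox_fit, km_at, km_fit,
                                 logrank_test, _cox_loglik)


class TestKaplanMeier:
    def test_all_events_is_empirical_fraction(self):
        km = km_fit([1, 2, 3, 4], [1, 1, 1, 1])
        assert km_at(km, 2.5).survival == pytest.approx(0.5)

    def test_hand_product_limit_with_censoring(self):
        # times {1,2,3,4}, events {1,0,1,1}: S(3) = (3/4)*(1/2) = 0.375
        km = km_fit([1, 2, 3, 4], [1, 0, 1, 1])
        est = km_at(km, 3.0)
        assert est.survival == pytest.approx(0.375)
        # Greenwood sum: 1/(4*3) + 1/(2*1); cll CI from it
        gw = 1 / 12 + 1 / 2
        se_theta = np.sqrt(gw) / abs(np.log(0.375))
        z = 1.959963984540054
        assert est.ci_low == pytest.approx(0.375 ** np.exp(z * se_theta))
        assert est.ci_high == pytest.approx(0.375 ** np.exp(-z * se_theta))

    def test_no_events_survival_stays_one(self):
        km = km_fit([1, 2, 3], [0, 0, 0])
        assert km_at(km, 3.0).survival == 1.0

    def test_before_first_event_degenerate_ci(self):
        km = km_fit([5, 6], [1, 1])
        est = km_at(km, 1.0)
        assert (est.survival, est.ci_low, est.ci_high) == (1.0, 1.0, 1.0)

    def test_beyond_support_flagged(self):
        km = km_fit([1, 2], [1, 0])
        assert km_at(km, 10.0).beyond_support

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_fit([], [])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 50.0), min_size=1, max_size=40))
    def test_no_censoring_equals_empirical_survival(self, times):
        """With every subject an event, KM is the empirical survival
        function exactly."""
        times = np.asarray(times)
        km = km_fit(times, np.ones(times.size, bool))
        for t in np.unique(times):
            assert km_at(km, t).survival == pytest.approx(
                np.mean(times > t), abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 200).round(1) + 0.1
        e = rng.random(200) < 0.7
        km = km_fit(t, e)
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter().fit(t, e)
        for q in (1.0, 3.0, 7.0):
            assert km_at(km, q).survival == pytest.approx(
                float(kmf.predict(q)), abs=1e-10)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.tile([1.0, 2, 3, 4, 5], 2)
        e = np.ones(10, bool)
        stat, p = logrank_test(t, e, np.repeat([0, 1], 5))
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        t = np.concatenate([rng.exponential(1.0, 500),
                            rng.exponential(4.0, 500)])
        stat, p = logrank_test(t, np.ones(1000, bool), np.repeat([0, 1], 500))
        assert p < 0.001

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


def _simulate_ph(rng, n, beta, censor_rate=0.0):
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-beta * x))
    if censor_rate > 0:
        c = rng.exponential(1.0 / censor_rate, n)
        e = t <= c
        t = np.minimum(t, c)
    else:
        e = np.ones(n, bool)
    return x[:, None], t, e


class TestCox:
    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3000, 1))
        t = rng.exponential(1.0, 3000)   # independent of x
        fit = cox_fit(x, t, np.ones(3000, bool))
        assert abs(fit.coef[0]) < 3 * fit.se[0]

    def test_recovers_true_hr_2(self):
        rng = np.random.default_rng(6)
        x = np.repeat([0.0, 1.0], 1000)[:, None]
        t = rng.exponential(np.exp(-np.log(2.0) * x[:, 0]))
        fit = cox_fit(x, t, np.ones(2000, bool))
        assert fit.coef[0] == pytest.approx(np.log(2.0), rel=0.10)

    def test_grid_search_oracle_n5(self):
        """Newton solution matches brute-force maximization of the
        partial likelihood on a tiny dataset to 1e-4."""
        x = np.array([0.8, -0.6, 0.1, 1.2, -1.1])[:, None]
        t = np.array([4.0, 2.0, 6.0, 1.0, 5.0])
        e = np.array([1, 1, 0, 1, 1], bool)
        fit = cox_fit(x, t, e)
        grid = np.arange(-4.0, 4.0, 0.01)
        lls = [_cox_loglik(np.array([b]), x, t, e, "efron")[0] for b in grid]
        best = grid[int(np.argmax(lls))]
        fine = np.arange(best - 0.011, best + 0.011, 1e-5)
        lls = [_cox_loglik(np.array([b]), x, t, e, "efron")[0] for b in fine]
        assert fit.coef[0] == pytest.approx(fine[int(np.argmax(lls))], abs=1e-4)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(7)
        X, t, e = _simulate_ph(rng, 150, 0.8, censor_rate=0.3)
        assert np.unique(t[e]).size == e.sum()  # no tied event times
        f1 = cox_fit(X, t, e, ties="efron")
        f2 = cox_fit(X, t, e, ties="breslow")
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-10)
        np.testing.assert_allclose(f1.se, f2.se, atol=1e-10)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(8)
        X, t, e = _simulate_ph(rng, 200, 0.5)
        base = cox_fit(X, t, e)
        shifted = cox_fit(X + 7.0, t, e)
        scaled = cox_fit(X * 3.0, t, e)
        assert shifted.coef[0] == pytest.approx(base.coef[0], abs=1e-7)
        assert scaled.coef[0] == pytest.approx(base.coef[0] / 3.0, abs=1e-7)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(250, 2))
        t = np.ceil(rng.exponential(np.exp(-(0.6 * x[:, 0] - 0.4 * x[:, 1]))) * 4) / 4
        e = rng.random(250) < 0.8
        fit = cox_fit(x, t, e)
        import pandas as pd
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"a": x[:, 0], "b": x[:, 1], "t": t, "e": e})
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values,
                                   atol=1e-5)

    def test_perfect_separation_diagnosed(self):
        # covariate orders events perfectly: monotone likelihood
        x = np.linspace(-2, 2, 20)[:, None]
        t = np.argsort(np.argsort(-x[:, 0])) + 1.0
        with pytest.raises(CoxConvergenceError):
            cox_fit(x, t, np.ones(20, bool))

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.ones((10, 1)), np.arange(1, 11.0), np.ones(10, bool))

    def test_covariance_symmetric_psd_and_ci_brackets_hr(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(300, 3))
        t = rng.exponential(np.exp(-x @ np.array([0.3, -0.2, 0.1])))
        fit = cox_fit(x, t, np.ones(300, bool))
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-12)
        assert np.all(fit.ci_low <= fit.hr) and np.all(fit.hr <= fit.ci_high)

    def test_breslow_baseline_recovers_exponential_hazard(self):
        rng = np.random.default_rng(11)
        X, t, e = _simulate_ph(rng, 4000, 0.5)
        fit = cox_fit(X, t, e)
        et, h0 = breslow_cumulative_hazard(X, t, e, fit.coef)
        # true baseline cumulative hazard at x=0 is t itself
        assert breslow_hazard_at(et, h0, 0.5) == pytest.approx(0.5, rel=0.1)
        assert breslow_hazard_at(et, h0, 1.0) == pytest.approx(1.0, rel=0.1)
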