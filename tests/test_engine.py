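"""Scoring-engine tests: transform DSL, PI/MI/TE, survival composition."""

import math

import numpy as np
import pytest

from predictval.engine import (CoefficientError, RangeError, MI_A_DEFAULT,
                               MI_B_DEFAULT, breast_survival,
                               coefficient_set_from_dict, compute_mi,
                               compute_pi, compute_te, other_survival,
                               predict_overall_survival)

from conftest import LAMBDA_BREAST, LAMBDA_OTHER, exponential_baseline, make_record


class TestLoadCoefficients:
    def test_shipped_v21_has_two_strata(self, v21_coeffs):
        assert v21_coeffs.version == "2.1"
        assert set(v21_coeffs.pi_terms) == {"positive", "negative"}
        assert set(v21_coeffs.baseline_breast) == {"positive", "negative"}

    def test_missing_trastuzumab_entry_rejected(self, toy_coeffs):
        d = {"version": "t", "pi_terms": {},
             "baseline_breast": {"positive": exponential_baseline(0.01)},
             "baseline_other": exponential_baseline(0.01),
             "treatments": {"hormone": -0.4, "chemo": -0.2}}
        with pytest.raises(CoefficientError, match="trastuzumab"):
            coefficient_set_from_dict(d)

    def test_decreasing_baseline_table_rejected(self):
        d = {"version": "t", "pi_terms": {},
             "baseline_breast": {"positive": {
                 "kind": "table", "years": [1, 2, 3],
                 "log_cum_hazard": [-2.0, -2.5, -2.2]}},
             "baseline_other": exponential_baseline(0.01),
             "treatments": {"hormone": 0, "chemo": 0, "trastuzumab": 0}}
        with pytest.raises(CoefficientError, match="decreasing"):
            coefficient_set_from_dict(d)

    def test_unknown_field_in_term_rejected(self):
        d = {"version": "t",
             "pi_terms": {"positive": [{"covariate": "tumour_speed",
                                        "coefficient": 1.0}]},
             "baseline_breast": {"positive": exponential_baseline(0.01)},
             "baseline_other": exponential_baseline(0.01),
             "treatments": {"hormone": 0, "chemo": 0, "trastuzumab": 0}}
        with pytest.raises(CoefficientError, match="tumour_speed"):
            coefficient_set_from_dict(d)

    def test_unknown_keys_rejected(self):
        with pytest.raises(CoefficientError, match="extra"):
            coefficient_set_from_dict({"version": "t", "extra": 1,
                                       "baseline_breast": {},
                                       "baseline_other": {},
                                       "treatments": {}})


class TestPI:
    def test_zero_nodes_gives_zero_pi(self, toy_coeffs):
        assert compute_pi(make_record(nodes=0), toy_coeffs) == 0.0

    def test_three_nodes(self, toy_coeffs):
        # 0.5 * ln(4)
        pi = compute_pi(make_record(nodes=3), toy_coeffs)
        assert pi == pytest.approx(0.5 * math.log(4), abs=1e-12)

    def test_additivity_of_terms(self, toy_coeffs):
        d = {"version": "two-term",
             "pi_terms": {"positive": [
                 {"covariate": "nodes", "coefficient": 0.5,
                  "transform": {"shift": 1, "power": 0}},
                 {"covariate": "size_mm", "coefficient": 0.01,
                  "transform": {"power": 1}, "center": 10.0},
             ]},
             "baseline_breast": {"positive": exponential_baseline(0.01)},
             "baseline_other": exponential_baseline(0.01),
             "treatments": {"hormone": 0, "chemo": 0, "trastuzumab": 0}}
        two = coefficient_set_from_dict(d)
        rec = make_record(nodes=3, size_mm=25.0)
        expected = 0.5 * math.log(4) + 0.01 * (25.0 - 10.0)
        assert compute_pi(rec, two) == pytest.approx(expected, abs=1e-12)

    def test_pi_increases_with_nodes_and_size(self, v21_coeffs):
        base = make_record(nodes=1, size_mm=15.0)
        more_nodes = make_record(nodes=5, size_mm=15.0)
        bigger = make_record(nodes=1, size_mm=40.0)
        pi0 = compute_pi(base, v21_coeffs)
        assert compute_pi(more_nodes, v21_coeffs) > pi0
        assert compute_pi(bigger, v21_coeffs) > pi0

    def test_out_of_range_strict_raises_and_clamp_warns(self, v21_coeffs, caplog):
        rec = make_record(age_years=95.0)
        with pytest.raises(RangeError, match="age_years"):
            compute_pi(rec, v21_coeffs, clamp=False)
        clamped = compute_pi(rec, v21_coeffs, clamp=True)
        at_bound = compute_pi(make_record(age_years=85.0), v21_coeffs)
        assert clamped == pytest.approx(at_bound)


class TestMI:
    def test_root_of_printed_formula(self, toy_coeffs):
        age0 = 10.0 * math.sqrt(MI_B_DEFAULT)
        assert abs(compute_mi(age0, toy_coeffs)) < 1e-12

    @pytest.mark.parametrize("age,expected", [
        (60.0, MI_A_DEFAULT * (36.0 - MI_B_DEFAULT)),      # ~ +0.123317
        (50.0, MI_A_DEFAULT * (25.0 - MI_B_DEFAULT)),      # ~ -0.644760
    ])
    def test_direct_arithmetic(self, toy_coeffs, age, expected):
        assert compute_mi(age, toy_coeffs) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_age_rejected(self, toy_coeffs):
        with pytest.raises(RangeError):
            compute_mi(0.0, toy_coeffs)

    def test_dsl_reproduces_hardcoded_mi(self):
        """The MI formula expressed as a DSL term evaluates identically
        to compute_mi (transform-DSL consistency)."""
        d = {"version": "mi-as-dsl",
             "pi_terms": {"positive": [{
                 "covariate": "age_years", "coefficient": MI_A_DEFAULT,
                 "transform": {"divisor": 10, "power": 2},
                 "center": MI_B_DEFAULT}]},
             "baseline_breast": {"positive": exponential_baseline(0.01)},
             "baseline_other": exponential_baseline(0.01),
             "treatments": {"hormone": 0, "chemo": 0, "trastuzumab": 0}}
        coeffs = coefficient_set_from_dict(d)
        for age in (25.0, 41.3, 58.5098, 60.0, 85.0):
            rec = make_record(age_years=age)
            assert compute_pi(rec, coeffs) == compute_mi(age, coeffs)


class TestTE:
    def test_no_treatment_is_zero(self, toy_coeffs):
        assert compute_te(make_record(), toy_coeffs) == 0.0

    def test_additivity(self, toy_coeffs):
        rec = make_record(hormone=True, chemo=True, er="positive")
        assert compute_te(rec, toy_coeffs) == pytest.approx(-0.6)

    def test_hormone_excluded_for_er_negative(self, toy_coeffs, caplog):
        rec = make_record(er="negative", hormone=True, chemo=True)
        import logging

        with caplog.at_level(logging.WARNING, logger="predictval.engine"):
            te = compute_te(rec, toy_coeffs)
        assert te == pytest.approx(-0.2)
        assert any("hormone" in m for m in caplog.messages)

    def test_radiotherapy_contributes_nothing(self, toy_coeffs):
        assert compute_te(make_record(radiotherapy=True), toy_coeffs) == 0.0


class TestSurvivalComposition:
    def test_no_accumulated_hazard_gives_one(self, toy_coeffs):
        assert breast_survival(0.0, 1.3, -0.2, "positive", toy_coeffs) == 1.0
        assert other_survival(0.0, 0.5, toy_coeffs) == 1.0

    def test_unit_cumulative_hazard(self, toy_coeffs):
        # choose PI+TE so that L0(t) + PI + TE = 0 at t = 5
        l0 = math.log(LAMBDA_BREAST * 5.0)
        bs = breast_survival(5.0, -l0, 0.0, "positive", toy_coeffs)
        assert bs == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_exponential_closed_forms(self, toy_coeffs):
        assert breast_survival(5.0, 0.0, 0.0, "positive", toy_coeffs) == \
            pytest.approx(math.exp(-0.1), abs=1e-12)
        assert other_survival(10.0, 0.0, toy_coeffs) == \
            pytest.approx(math.exp(-0.1), abs=1e-12)

    def test_overall_is_exact_product(self, toy_coeffs):
        pred = predict_overall_survival(
            make_record(nodes=2, chemo=True), toy_coeffs, horizons=(2.5, 5, 10))
        for b, o, s in zip(pred.breast_surv, pred.other_surv,
                           pred.overall_surv):
            assert s == b * o  # exact, not approximate

    def test_monotone_nonincreasing_in_t(self, v21_coeffs):
        rec = make_record(nodes=3, size_mm=30.0, grade=3, chemo=True)
        ts = np.linspace(0.5, 14.5, 60)
        pred = predict_overall_survival(rec, v21_coeffs, horizons=ts)
        for series in (pred.breast_surv, pred.other_surv, pred.overall_surv):
            arr = np.asarray(series)
            assert np.all(arr >= 0) and np.all(arr <= 1)
            assert np.all(np.diff(arr) <= 1e-15)

    def test_t_outside_support_raises(self, v21_coeffs):
        with pytest.raises(RangeError):
            breast_survival(20.0, 0.0, 0.0, "positive", v21_coeffs)
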