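import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st
from scipy import stats

from obesim.risk import (
    HealthState,
    LifeTable,
    PiecewiseHazard,
    StateError,
    assign_cv_event_type,
    background_mortality_rate,
    cancer_onset_rate,
    diabetes_complication_rates,
    framingham_cvd_10y,
    post_mi_hf_rate,
    ratchet_rate,
    risk10_to_rate,
    sample_event_time,
    secondary_cv_rate,
    t2d_onset_rate,
)


def _state(**kw):
    base = dict(
        factors={"bmi": 36.0, "wc": 110.0, "hdl": 45.0, "tg": 150.0,
                 "sbp": 125.0, "fpg": 100.0},
        age=55.0,
    )
    base.update(kw)
    return HealthState(**base)


class TestFramingham:
    def test_spreadsheet_evaluation_male(self, params):
        # independent hand computation of the transcribed Cox equation
        # (male, age 55, HDL 45, TG 150 -> TC = 115 + 45 + 30 = 190,
        #  SBP 125 untreated, smoker, no diabetes)
        state = _state()
        risk = framingham_cvd_10y(state, "male", smoker=True, params=params)
        assert risk == pytest.approx(0.19594945423175103, rel=1e-12)

    def test_spreadsheet_evaluation_female(self, params):
        state = _state(
            factors={"bmi": 34.0, "wc": 100.0, "hdl": 55.0, "tg": 120.0,
                     "sbp": 140.0, "fpg": 100.0},
            age=60.0, t2d=True,
        )
        risk = framingham_cvd_10y(state, "female", smoker=False, params=params)
        assert risk == pytest.approx(0.2072377981552228, rel=1e-12)

    def test_risk_increases_with_sbp(self, params):
        lo, hi = _state(), _state()
        lo.factors["sbp"], hi.factors["sbp"] = 120.0, 150.0
        assert framingham_cvd_10y(hi, "male", False, params) > framingham_cvd_10y(
            lo, "male", False, params
        )

    def test_diabetes_raises_risk(self, params):
        assert framingham_cvd_10y(_state(t2d=True), "male", False, params) > (
            framingham_cvd_10y(_state(), "male", False, params)
        )

    def test_requires_cv_free_state(self, params):
        with pytest.raises(StateError):
            framingham_cvd_10y(_state(prior_primary_cv=True), "male", False, params)

    def test_missing_covariate_rejected(self, params):
        state = _state(factors={"hdl": 45.0})
        with pytest.raises(ValueError, match="covariate"):
            framingham_cvd_10y(state, "male", False, params)


class TestSecondaryCV:
    def test_requires_prior_event(self, params):
        with pytest.raises(StateError):
            secondary_cv_rate(_state(), params)

    def test_rate_nonnegative_and_age_scaled(self, params):
        young = secondary_cv_rate(_state(prior_primary_cv=True, age=50.0), params)
        old = secondary_cv_rate(_state(prior_primary_cv=True, age=75.0), params)
        assert 0 <= young < old


class TestRiskConversion:
    @pytest.mark.parametrize("p10, rate", [
        (0.0, 0.0),
        (1.0 - math.exp(-1.0), 0.1),
        (0.2, 0.022314355131420972),
    ])
    def test_closed_form(self, p10, rate):
        assert risk10_to_rate(p10) == pytest.approx(rate, abs=1e-12)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            risk10_to_rate(1.0)


class TestEventTimeSampling:
    def test_constant_rate_closed_form(self):
        hz = PiecewiseHazard(np.array([0.0, math.inf]), np.array([0.2]))
        assert sample_event_time(hz, math.exp(-0.2)) == pytest.approx(1.0)

    def test_piecewise_inversion_by_hand(self):
        # H(t) = 0.1 t on [0,1); 0.1 + 0.2 (t-1) after; H(t)=0.25 at t=1.75
        hz = PiecewiseHazard(np.array([0.0, 1.0, math.inf]), np.array([0.1, 0.2]))
        assert sample_event_time(hz, math.exp(-0.25)) == pytest.approx(1.75)

    def test_zero_hazard_yields_no_event(self):
        hz = PiecewiseHazard(np.array([0.0, 50.0]), np.array([0.0]))
        assert sample_event_time(hz, 0.5) is None

    def test_censoring_at_support_end(self):
        hz = PiecewiseHazard(np.array([0.0, 1.0]), np.array([0.1]))
        assert sample_event_time(hz, math.exp(-0.25)) is None

    def test_invalid_uniform_rejected(self):
        hz = PiecewiseHazard(np.array([0.0, 1.0]), np.array([0.1]))
        with pytest.raises(ValueError):
            sample_event_time(hz, 0.0)

    def test_exponential_distribution_recovered(self, rng):
        """KS test of sampled times against the exponential closed form."""
        lam = 0.35
        hz = PiecewiseHazard(np.array([0.0, math.inf]), np.array([lam]))
        u = rng.random(100_000)
        times = np.array([sample_event_time(hz, ui) for ui in u])
        res = stats.kstest(times, "expon", args=(0.0, 1.0 / lam))
        assert res.pvalue > 0.01

    def test_piecewise_distribution_recovered(self, rng):
        """Empirical survival at knots matches exp(-H(t)) for a 2-piece hazard."""
        hz = PiecewiseHazard(np.array([0.0, 2.0, math.inf]), np.array([0.05, 0.4]))
        u = rng.random(100_000)
        times = np.array([sample_event_time(hz, ui) for ui in u])
        for t, cum in ((1.0, 0.05), (2.0, 0.10), (3.0, 0.50)):
            emp = (times > t).mean()
            assert emp == pytest.approx(math.exp(-cum), abs=0.005)


class TestRatchet:
    def test_below_baseline_unchanged(self):
        assert ratchet_rate(0.01, 1.10, bmi=35.0, bmi0=40.0) == 0.01

    def test_arithmetic_above_baseline(self):
        assert ratchet_rate(0.01, 1.10, bmi=42.0, bmi0=40.0) == pytest.approx(0.0121)

    def test_unit_hazard_ratio_is_identity(self):
        for bmi in (20.0, 40.0, 60.0):
            assert ratchet_rate(0.01, 1.0, bmi, 40.0) == 0.01

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        bmi_a=st.floats(15, 70), bmi_b=st.floats(15, 70),
        hr=st.floats(1.0, 1.5), base=st.floats(0, 0.5),
    )
    def test_monotone_and_never_below_baseline(self, bmi_a, bmi_b, hr, base):
        lo, hi = sorted((bmi_a, bmi_b))
        assert ratchet_rate(base, hr, lo, 40.0) <= ratchet_rate(base, hr, hi, 40.0)
        assert ratchet_rate(base, hr, lo, 40.0) >= base


class TestCVEventType:
    def test_cumulative_lookup_secondary(self, params):
        p = params.with_overrides({
            "risk_coefficients.cv_event_type_split.secondary.mi": 0.6,
            "risk_coefficients.cv_event_type_split.secondary.stroke": 0.4,
        })
        assert assign_cv_event_type(False, 0.7, p) == "stroke"
        assert assign_cv_event_type(False, 0.5, p) == "mi"

    def test_primary_hf_band(self, params):
        split = params.risk_coefficients.cv_event_type_split["primary"]
        u = split["mi"] + split["stroke"] + split["hf"] / 2
        assert assign_cv_event_type(True, u, params) == "hf"

    def test_degenerate_split(self, params):
        p = params.with_overrides({
            "risk_coefficients.cv_event_type_split.secondary.mi": 1.0,
            "risk_coefficients.cv_event_type_split.secondary.stroke": 0.0,
        })
        for u in (0.001, 0.5, 0.999):
            assert assign_cv_event_type(False, u, p) == "mi"


class TestT2DOnset:
    @pytest.mark.parametrize("equation", ["regards", "san_antonio", "framingham"])
    def test_glycemia_monotonicity(self, params, equation):
        lo, hi = _state(), _state()
        lo.factors["fpg"], hi.factors["fpg"] = 90.0, 115.0
        assert t2d_onset_rate(hi, "male", False, params, equation) > t2d_onset_rate(
            lo, "male", False, params, equation
        )

    def test_reference_vector_gives_base_rate(self, params):
        eq = params.risk_coefficients.t2d_equations["regards"]
        state = _state(
            factors={"bmi": 32.0, "wc": 110.0, "hdl": 50.0, "tg": 140.0,
                     "sbp": 125.0, "fpg": 100.0},
            age=46.0,
        )
        rate = t2d_onset_rate(state, "female", False, params, "regards")
        assert rate == pytest.approx(eq.base_annual_rate, rel=1e-12)

    def test_log_linear_scaling_matches_hand_computation(self, params):
        eq = params.risk_coefficients.t2d_equations["regards"]
        state = _state()
        state.factors["fpg"] = 115.0
        expected = eq.base_annual_rate * math.exp(
            eq.coefficients["fpg"] * 15.0
            + eq.coefficients["bmi"] * (36.0 - 32.0)
            + eq.coefficients["age"] * (55.0 - 46.0)
            + eq.coefficients["tg"] * 10.0
            + eq.coefficients["hdl"] * -5.0
            + eq.coefficients["male"]
        )
        got = t2d_onset_rate(state, "male", False, params, "regards")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_existing_t2d_rejected(self, params):
        with pytest.raises(StateError):
            t2d_onset_rate(_state(t2d=True), "male", False, params)

    def test_unknown_equation_rejected(self, params):
        with pytest.raises(KeyError):
            t2d_onset_rate(_state(), "male", False, params, "dppos")


class TestPostMIHF:
    def test_requires_prior_mi(self, params):
        with pytest.raises(StateError):
            post_mi_hf_rate(_state(), params)

    def test_rejected_when_hf_present(self, params):
        with pytest.raises(StateError):
            post_mi_hf_rate(_state(prior_mi=True, hf=True), params)

    def test_configured_rate_returned(self, params):
        assert post_mi_hf_rate(_state(prior_mi=True), params) == (
            params.risk_coefficients.post_mi_hf_annual_rate
        )

    def test_zero_rate_config(self, params):
        p = params.with_overrides({"risk_coefficients.post_mi_hf_annual_rate": 0.0})
        assert post_mi_hf_rate(_state(prior_mi=True), p) == 0.0


class TestCancer:
    def test_sex_specific_type_support(self, params):
        _, male_dist = cancer_onset_rate(_state(), "male", 40.0, params)
        assert not set(male_dist) & {"endometrial", "breast"}
        _, female_dist = cancer_onset_rate(_state(), "female", 40.0, params)
        assert sum(female_dist.values()) == pytest.approx(1.0)

    def test_existing_cancer_rejected(self, params):
        with pytest.raises(StateError):
            cancer_onset_rate(_state(cancer_type="colon"), "male", 40.0, params)

    def test_bmi_below_baseline_keeps_baseline_rate(self, params):
        state = _state()
        state.factors["bmi"] = 30.0  # below baseline 40
        rate, _ = cancer_onset_rate(state, "male", 40.0, params)
        band = [b for b in params.baseline_rates.cancer.age_bands
                if b.lower <= state.age < b.upper][0]
        assert rate == pytest.approx(band.rate)


class TestDiabetesComplications:
    def test_requires_t2d(self, params):
        with pytest.raises(StateError):
            diabetes_complication_rates(_state(), params)

    def test_all_four_rates_nonnegative(self, params):
        rates = diabetes_complication_rates(_state(t2d=True), params)
        assert set(rates) == {"foot_ulcer", "amputation", "retinopathy", "renal"}
        assert all(r >= 0 for r in rates.values())

    def test_rate_doubling_doubles_incidence(self, params, rng):
        """Monte-Carlo proportionality of first-year incidence in the rate."""
        base = params.baseline_rates.diabetes_complications["retinopathy"]
        u = rng.random(50_000)
        inc1 = np.mean(-np.log(u) / base <= 1.0)
        inc2 = np.mean(-np.log(u) / (2 * base) <= 1.0)
        expected1 = 1 - math.exp(-base)
        expected2 = 1 - math.exp(-2 * base)
        assert inc1 == pytest.approx(expected1, abs=0.005)
        assert inc2 == pytest.approx(expected2, abs=0.005)
        assert inc2 / inc1 == pytest.approx(expected2 / expected1, rel=0.1)


class TestBackgroundMortality:
    def test_zero_cv_share_equals_raw_table(self, params):
        p = params.with_overrides({"risk_coefficients.cv_death_share": 0.0})
        lt = LifeTable.from_params(p)
        raw = lt._table
        mid = raw.iloc[len(raw) // 2]
        assert lt.rate(float(mid["age"]), "male") == pytest.approx(float(mid["male"]))

    def test_rate_nondecreasing_in_age(self, params):
        lt = LifeTable.from_params(params)
        rates = [lt.rate(a, "female") for a in range(30, 100)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_age_beyond_table_clamps_to_final_row(self, params):
        lt = LifeTable.from_params(params)
        assert background_mortality_rate(200.0, "male", params, lt) == pytest.approx(
            lt.rate(110.0, "male")
        )

    def test_cv_share_scales_rate_down(self, params):
        p0 = params.with_overrides({"risk_coefficients.cv_death_share": 0.0})
        assert background_mortality_rate(70.0, "male", params) < (
            background_mortality_rate(70.0, "male", p0)
        )
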