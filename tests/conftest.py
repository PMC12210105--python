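import numpy as np
import pytest

from obesim import load_parameters
from obesim.engine import EventRecord, PatientHistory
from obesim.population import PatientProfile
from obesim.trajectory import build_phase_plan


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def quiet_params(params):
    """Parameters with every stochastic process silenced except treatment
    phases: no CV, T2D, cancer, OA, OSA or background mortality hazards."""
    overrides = {
        "risk_coefficients.secondary_cv.base_annual_rate": 0.0,
        "risk_coefficients.post_mi_hf_annual_rate": 0.0,
        "risk_coefficients.cv_death_share": 1.0,
        "baseline_rates.osteoarthritis": 0.0,
        "baseline_rates.sleep_apnea": 0.0,
    }
    for c in ("foot_ulcer", "amputation", "retinopathy", "renal"):
        overrides[f"baseline_rates.diabetes_complications.{c}"] = 0.0
    for i in range(len(params.baseline_rates.cancer.age_bands)):
        overrides[f"baseline_rates.cancer.age_bands.{i}.rate"] = 0.0
    for eq in ("regards", "san_antonio", "framingham"):
        overrides[f"risk_coefficients.t2d_equations.{eq}.base_annual_rate"] = 0.0
    return params.with_overrides(overrides)


@pytest.fixture
def profile():
    return PatientProfile(
        id=0, sex="male", age=46.0, smoker=False, bmi0=40.0, wc0=115.0,
        hdl0=48.0, tg0=150.0, sbp0=125.0, fpg0=102.0,
        history=frozenset({"hypertension"}),
    )


@pytest.fixture
def female_profile():
    return PatientProfile(
        id=1, sex="female", age=50.0, smoker=True, bmi0=36.0, wc0=108.0,
        hdl0=55.0, tg0=130.0, sbp0=122.0, fpg0=98.0, history=frozenset(),
    )


def make_history(profile, params, arm="tzp10", t_discontinue=None,
                 events=(), death_time=None, horizon=None):
    """Hand-built patient history for economics/utility unit tests."""
    if horizon is None:
        horizon = params.horizon_years(profile.age)
    plan = build_phase_plan(arm, t_discontinue, params)
    evs = list(events)
    if death_time is None:
        evs.append(EventRecord(horizon, "horizon_end"))
    return PatientHistory(
        profile=profile, arm=arm, plan=plan, horizon=horizon,
        events=evs, death_time=death_time,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
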