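"""Time-varying complication and mortality hazards, and event-time sampling.

Primary cardiovascular risk comes from the Framingham 10-year general-CVD
Cox equation (coefficients transcribed from its source publication),
converted to a constant annual rate re-evaluated at every grid update.
Secondary CV risk, post-MI heart failure, T2D onset (three switchable
incidence equations), diabetes complications, six obesity-linked cancers,
osteoarthritis and sleep apnea are configured annual rates; OA, sleep apnea
and cancer hazards ratchet upward with BMI above baseline but never fall
below their baseline value.  Background mortality is a life table with the
CV-death share removed (CV deaths are modelled explicitly).
"""

from __future__ import annotations

import importlib.resources
import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ParameterSet
from .population import PatientProfile

logger = logging.getLogger(__name__)

CV_EVENT_TYPES = ("mi", "stroke", "hf", "mi_hf", "stroke_hf")
DIABETES_COMPLICATIONS = ("foot_ulcer", "amputation", "retinopathy", "renal")


class StateError(RuntimeError):
    """A risk function was called on a state violating its precondition."""


@dataclass
class HealthState:
    """Mutable condition set tracked through one patient's simulation."""

    alive: bool = True
    t2d: bool = False
    prior_primary_cv: bool = False
    hf: bool = False
    prior_mi: bool = False
    prior_stroke: bool = False
    cancer_type: str = "none"
    osteoarthritis: bool = False
    sleep_apnea: bool = False
    diabetes_complications: set[str] = field(default_factory=set)
    factors: dict[str, float] = field(default_factory=dict)
    age: float = 0.0

    @classmethod
    def from_profile(cls, profile: PatientProfile) -> "HealthState":
        h = profile.history
        return cls(
            t2d="t2d" in h,
            prior_primary_cv="prior_cv_event" in h,
            hf="hf" in h,
            osteoarthritis="osteoarthritis" in h,
            sleep_apnea="sleep_apnea" in h,
            age=profile.age,
        )

    def snapshot(self) -> "HealthState":
        return replace(
            self,
            diabetes_complications=set(self.diabetes_complications),
            factors=dict(self.factors),
        )


@dataclass(frozen=True)
class PiecewiseHazard:
    """Piecewise-constant hazard: ``rates[i]`` applies on
    [breakpoints[i], breakpoints[i+1]); the last rate extends to the final
    breakpoint, which bounds the support (no events beyond it)."""

    breakpoints: np.ndarray  # yr, strictly increasing, len = len(rates) + 1
    rates: np.ndarray        # events/yr

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "rates", r)
        if len(bp) != len(r) + 1:
            raise ValueError("need len(breakpoints) == len(rates) + 1")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("rates must be >= 0")


def sample_event_time(hazard: PiecewiseHazard, u: float) -> float | None:
    """Invert the cumulative hazard: smallest t with H(t) = -ln(u), or None
    if the total hazard over the support never reaches -ln(u)."""
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie in (0, 1)")
    target = -math.log(u)
    h = 0.0
    bp, rates = hazard.breakpoints, hazard.rates
    for i, rate in enumerate(rates):
        if rate <= 0.0:
            continue  # no hazard accumulates on this interval
        seg = rate * (bp[i + 1] - bp[i])
        if h + seg >= target:
            return float(bp[i] + (target - h) / rate)
        h += seg
    return None


def risk10_to_rate(p10: float) -> float:
    """Constant annual hazard equivalent to a 10-year event probability."""
    if not 0.0 <= p10 < 1.0:
        raise ValueError("p10 must lie in [0, 1)")
    return -math.log1p(-p10) / 10.0


def _total_cholesterol(state: HealthState, params: ParameterSet) -> float:
    # TC is not tracked; reconstruct via inverse Friedewald with assumed LDL.
    return (
        params.risk_coefficients.assumed_ldl
        + state.factors["hdl"]
        + state.factors["tg"] / 5.0
    )


def framingham_cvd_10y(
    state: HealthState, sex: str, smoker: bool, params: ParameterSet
) -> float:
    """10-year primary CVD risk for a CV-event-free patient."""
    if state.prior_primary_cv:
        raise StateError("Framingham primary risk is for patients without CV history")
    for cov in ("hdl", "tg", "sbp"):
        if cov not in state.factors:
            raise ValueError(f"state is missing covariate {cov!r}")
    c = params.risk_coefficients.framingham_cvd[sex]
    sbp = state.factors["sbp"]
    treated = sbp > params.simulation.lisinopril_sbp_threshold
    sbp_beta = c.ln_sbp_treated if treated else c.ln_sbp_untreated
    lp = (
        c.ln_age * math.log(state.age)
        + c.ln_total_chol * math.log(_total_cholesterol(state, params))
        + c.ln_hdl * math.log(state.factors["hdl"])
        + sbp_beta * math.log(sbp)
        + c.smoker * float(smoker)
        + c.diabetes * float(state.t2d)
    )
    risk = 1.0 - c.s0_10 ** math.exp(lp - c.mean_lp)
    return min(max(risk, 1e-12), 1.0 - 1e-12)


def secondary_cv_rate(state: HealthState, params: ParameterSet) -> float:
    """Annual secondary CV event rate for a patient with CV history."""
    if not state.prior_primary_cv:
        raise StateError("secondary CV risk requires a prior primary CV event")
    c = params.risk_coefficients.secondary_cv
    return c.base_annual_rate * math.exp(
        c.log_hr_per_year_age * (state.age - c.ref_age)
    )


def t2d_onset_rate(
    state: HealthState, sex: str, smoker: bool, params: ParameterSet,
    equation: str | None = None,
) -> float:
    """Annual T2D onset rate from the selected incidence equation
    (default from config; alternates: san_antonio, framingham)."""
    if state.t2d:
        raise StateError("T2D onset rate requested for a patient who has T2D")
    name = equation or params.risk_coefficients.t2d_equation_default
    if name not in params.risk_coefficients.t2d_equations:
        raise KeyError(
            f"unknown T2D equation {name!r}; have "
            f"{sorted(params.risk_coefficients.t2d_equations)}"
        )
    eq = params.risk_coefficients.t2d_equations[name]
    covariates = {
        "fpg": state.factors["fpg"], "bmi": state.factors["bmi"],
        "age": state.age, "tg": state.factors["tg"], "hdl": state.factors["hdl"],
        "sbp": state.factors["sbp"], "smoker": float(smoker),
        "male": float(sex == "male"),
    }
    lp = sum(
        beta * (covariates[k] - eq.reference[k])
        for k, beta in eq.coefficients.items()
    )
    return eq.base_annual_rate * math.exp(lp)


def ratchet_rate(
    baseline_rate: float, hr_per_unit: float, bmi: float, bmi0: float
) -> float:
    """BMI-ratcheted hazard: scales up with BMI above baseline, never down."""
    if baseline_rate < 0:
        raise ValueError("baseline_rate must be >= 0")
    if hr_per_unit <= 0:
        raise ValueError("hr_per_unit must be > 0")
    return baseline_rate * hr_per_unit ** max(0.0, bmi - bmi0)


def assign_cv_event_type(
    is_primary: bool, u: float, params: ParameterSet
) -> str:
    """Pick the CV event type from the configured primary/secondary split."""
    stratum = "primary" if is_primary else "secondary"
    split = params.risk_coefficients.cv_event_type_split[stratum]
    cum = 0.0
    items = list(split.items())
    for kind, p in items:
        cum += p
        if u < cum:
            return kind
    return items[-1][0]


def post_mi_hf_rate(state: HealthState, params: ParameterSet) -> float:
    """Annual HF onset rate after MI; persists until death."""
    if not state.prior_mi:
        raise StateError("post-MI HF risk requires a prior MI")
    if state.hf:
        raise StateError("patient already has HF")
    return params.risk_coefficients.post_mi_hf_annual_rate


def cancer_onset_rate(
    state: HealthState, sex: str, bmi0: float, params: ParameterSet
) -> tuple[float, dict[str, float]]:
    """(total annual onset rate over the sex-appropriate types, type
    distribution).  The baseline age-band rate is BMI-ratcheted."""
    if state.cancer_type != "none":
        raise StateError("patients develop at most one cancer")
    cfg = params.baseline_rates.cancer
    base = 0.0
    for band in cfg.age_bands:
        if band.lower <= state.age < band.upper:
            base = band.rate
            break
    hr = params.risk_coefficients.hazard_ratios_per_bmi_unit["cancer"]
    rate = ratchet_rate(base, hr, state.factors["bmi"], bmi0)
    return rate, dict(cfg.type_distribution[sex])


def diabetes_complication_rates(
    state: HealthState, params: ParameterSet
) -> dict[str, float]:
    """Constant annual incidence of the four diabetes complications
    (independent; co-occurrence allowed), only once T2D is present."""
    if not state.t2d:
        raise StateError("diabetes complications require T2D")
    return dict(params.baseline_rates.diabetes_complications)


class LifeTable:
    """Background all-cause mortality by (age, sex), CV share removed."""

    def __init__(self, table: pd.DataFrame, cv_death_share: float):
        if not {"age", "male", "female"} <= set(table.columns):
            raise ValueError("life table needs columns age, male, female")
        self._table = table.sort_values("age").reset_index(drop=True)
        self._ages = self._table["age"].to_numpy(dtype=float)
        self._share = cv_death_share

    @classmethod
    def from_params(cls, params: ParameterSet) -> "LifeTable":
        name = params.life_table_file
        if os.path.exists(name):
            df = pd.read_csv(name)
        else:
            with importlib.resources.files("obesim.data").joinpath(name).open() as fh:
                df = pd.read_csv(fh)
        return cls(df, params.risk_coefficients.cv_death_share)

    def rate(self, age: float, sex: str) -> float:
        if age > self._ages[-1]:
            logger.warning("age %.1f beyond life table; clamped to final row", age)
        idx = int(np.clip(np.searchsorted(self._ages, age, side="right") - 1,
                          0, len(self._ages) - 1))
        raw = float(self._table.loc[idx, sex])
        return max(raw * (1.0 - self._share), 0.0)


def background_mortality_rate(
    age: float, sex: str, params: ParameterSet, life_table: LifeTable | None = None
) -> float:
    lt = life_table if life_table is not None else LifeTable.from_params(params)
    return lt.rate(age, sex)
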