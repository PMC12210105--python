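"""Cost accrual and discounting from a simulated patient history.

Ongoing costs (drug, program, concomitant medications, chronic follow-up and
management) accrue continuously and are discounted with the continuous-time
integral of the annual discount factor; one-time costs (hospitalisations,
lump follow-up, event costs) are discounted at the moment they occur.  The
ledger keeps the categories of the published results table: treatment, LSM
program, concomitant medications, CV events and HF, cancer, diabetes,
osteoarthritis, sleep apnea, and (societal scenario only) indirect costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import TZP_ARMS, ParameterSet
from .engine import PatientHistory
from .trajectory import bmi_at, factor_at

CATEGORIES = (
    "treatment", "lsm_program", "concomitant", "cv_events_hf", "cancer",
    "diabetes", "osteoarthritis", "sleep_apnea", "indirect",
)


@dataclass
class CostLedger:
    """Discounted USD by category; ``total`` is their sum."""

    by_category: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CATEGORIES}
    )

    def add(self, category: str, amount: float) -> None:
        if category not in self.by_category:
            raise KeyError(f"unknown cost category {category!r}")
        if amount < 0:
            raise ValueError("cost contributions must be >= 0")
        self.by_category[category] += amount

    @property
    def total(self) -> float:
        return sum(self.by_category.values())


def discount_factor(t: float, rate: float) -> float:
    """(1 + rate)^(-t): present value of one dollar at time t."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return (1.0 + rate) ** (-t)


def discounted_exposure(a: float, b: float, rate: float) -> float:
    """∫_a^b (1+rate)^(-t) dt — discounted person-time on [a, b]."""
    if b <= a:
        return 0.0
    if rate == 0.0:
        return b - a
    ln1r = math.log1p(rate)
    return (discount_factor(a, rate) - discount_factor(b, rate)) / ln1r


def _treatment_end(history: PatientHistory) -> float:
    t_disc = history.plan.t_discontinue
    end = history.end_time
    return min(t_disc, end) if t_disc is not None else end


def accrue_treatment_costs(history: PatientHistory, params: ParameterSet,
                           ledger: CostLedger | None = None) -> float:
    """Drug or program cost while on treatment, discounted; returns the
    discounted USD and (if given) posts it to the ledger."""
    r = params.simulation.discount_rate_costs
    stop = _treatment_end(history)
    if history.arm in TZP_ARMS:
        amount = params.costs.tirzepatide_annual * discounted_exposure(0.0, stop, r)
        category = "treatment"
    else:
        amount = (
            params.costs.lsm_year1 * discounted_exposure(0.0, min(1.0, stop), r)
            + params.costs.lsm_subsequent * discounted_exposure(1.0, stop, r)
        )
        category = "lsm_program"
    if ledger is not None:
        ledger.add(category, amount)
    return amount


def concomitant_medication_set(
    sbp: float, prior_cv_or_hf: bool, t2d: bool, fpg: float, params: ParameterSet
) -> set[str]:
    """Medications triggered by the current state: lisinopril while
    SBP > 130 mm Hg (strict), simvastatin after any CV event or HF,
    metformin/glimepiride once T2D or FPG > 126 mg/dL (then lifelong)."""
    meds = set()
    if sbp > params.simulation.lisinopril_sbp_threshold:
        meds.add("lisinopril")
    if prior_cv_or_hf:
        meds.add("simvastatin")
    if t2d or fpg > params.simulation.metformin_fpg_threshold:
        meds.add("metformin_glimepiride")
    return meds


def _segment_breakpoints(history: PatientHistory) -> list[float]:
    end = history.end_time
    plan = history.plan
    pts = {0.0, end, min(plan.t_initial_end, end), min(plan.t_attenuated_end, end)}
    if plan.t_discontinue is not None:
        pts |= {min(plan.t_discontinue, end), min(plan.t_regain_end, end)}
    for e in history.events:
        if e.time < end:
            pts.add(e.time)
    from .trajectory import update_grid

    for g in update_grid(history.horizon):
        if g <= end:
            pts.add(float(g))
    return sorted(pts)


def accrue_concomitant_costs(history: PatientHistory, params: ParameterSet,
                             ledger: CostLedger) -> None:
    r = params.simulation.discount_rate_costs
    end = history.end_time
    if end <= 0:
        return
    profile, plan = history.profile, history.plan
    pts = _segment_breakpoints(history)

    # lifelong triggers
    t2d_onsets = history.events_of("t2d_onset")
    t_t2d = 0.0 if "t2d" in profile.history else (
        t2d_onsets[0].time if t2d_onsets else math.inf
    )
    cv_times = [e.time for e in history.events_of("cv_event", "hf_onset")]
    baseline_cv = "prior_cv_event" in profile.history or "hf" in profile.history
    t_statin = 0.0 if baseline_cv else (min(cv_times) if cv_times else math.inf)

    t_metformin = t_t2d
    lisinopril_exposure = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        sbp = factor_at(a, "sbp", profile, plan, params)
        if sbp > params.simulation.lisinopril_sbp_threshold:
            lisinopril_exposure += discounted_exposure(a, b, r)
        fpg = factor_at(a, "fpg", profile, plan, params)
        if fpg > params.simulation.metformin_fpg_threshold:
            t_metformin = min(t_metformin, a)

    amount = params.costs.lisinopril_annual * lisinopril_exposure
    if t_statin < end:
        amount += params.costs.simvastatin_annual * discounted_exposure(t_statin, end, r)
    if t_metformin < end:
        amount += params.costs.metformin_glimepiride_annual * discounted_exposure(
            t_metformin, end, r
        )
    ledger.add("concomitant", amount)


def _bmi_above_threshold_intervals(
    history: PatientHistory, params: ParameterSet, threshold: float
) -> list[tuple[float, float]]:
    """Exact intervals where the piecewise-linear BMI path is >= threshold."""
    profile, plan = history.profile, history.plan
    end = history.end_time
    knots = {0.0, end, min(plan.t_initial_end, end), min(plan.t_attenuated_end, end)}
    if plan.t_discontinue is not None:
        knots |= {min(plan.t_discontinue, end), min(plan.t_regain_end, end)}
    knots = sorted(knots)
    intervals: list[tuple[float, float]] = []
    for a, b in zip(knots[:-1], knots[1:]):
        if b <= a:
            continue
        ya = bmi_at(a, profile, plan, params) - threshold
        yb = bmi_at(b, profile, plan, params) - threshold
        if ya >= 0 and yb >= 0:
            intervals.append((a, b))
        elif ya >= 0 > yb:
            intervals.append((a, a + (b - a) * ya / (ya - yb)))
        elif yb >= 0 > ya:
            intervals.append((a + (b - a) * ya / (ya - yb), b))
    return intervals


def accrue_event_costs(history: PatientHistory, params: ParameterSet,
                       ledger: CostLedger) -> None:
    """Acute, follow-up, chronic-management and terminal costs implied by the
    event history (see the published cost table for the per-item amounts)."""
    r = params.simulation.discount_rate_costs
    c = params.costs
    end = history.end_time

    def ongoing(start: float, annual: float) -> float:
        return annual * discounted_exposure(start, end, r)

    # baseline chronic conditions accrue from model entry
    if "hf" in history.profile.history:
        ledger.add("cv_events_hf", ongoing(0.0, c.hf_annual_followup))
    if "osteoarthritis" in history.profile.history:
        ledger.add("osteoarthritis", ongoing(0.0, c.osteoarthritis_annual))
    if "sleep_apnea" in history.profile.history:
        ledger.add("sleep_apnea", ongoing(0.0, c.sleep_apnea_annual))

    for e in history.events:
        t = e.time
        df = discount_factor(t, r)
        if e.kind == "cv_event":
            parts = e.detail["subtype"].split("_")
            if "mi" in parts:
                ledger.add("cv_events_hf", df * (c.mi_hospitalization + c.mi_first_3mo))
                ledger.add("cv_events_hf", ongoing(t + 0.25, c.mi_annual_followup))
            if "stroke" in parts:
                ledger.add("cv_events_hf",
                           df * (c.stroke_hospitalization + c.stroke_first_3mo))
                ledger.add("cv_events_hf", ongoing(t + 0.25, c.stroke_annual_followup))
            if "hf" in parts:
                ledger.add("cv_events_hf", ongoing(t, c.hf_annual_followup))
        elif e.kind == "cv_event_fatal":
            ledger.add("cv_events_hf", df * c.cv_death)
        elif e.kind == "hf_onset":
            ledger.add("cv_events_hf", ongoing(t, c.hf_annual_followup))
        elif e.kind == "diabetes_complication":
            comp = e.detail["subtype"]
            if comp == "foot_ulcer":
                ledger.add("diabetes", df * c.foot_ulcer)
            elif comp == "amputation":
                ledger.add("diabetes", df * c.amputation)
            elif comp == "retinopathy":
                ledger.add("diabetes", ongoing(t, c.retinopathy_annual))
            elif comp == "renal":
                ledger.add("diabetes", ongoing(t, c.renal_annual))
            else:
                raise KeyError(f"no cost configured for diabetes complication {comp!r}")
        elif e.kind == "cancer_onset":
            cc = c.cancer[e.detail["type"]]
            first_end = min(t + 1.0, end)
            ledger.add("cancer", cc.first_year * discounted_exposure(t, first_end, r))
            ledger.add("cancer",
                       cc.subsequent_annual * discounted_exposure(t + 1.0, end, r))
        elif e.kind == "cancer_death":
            ledger.add("cancer", df * c.cancer_terminal)
        elif e.kind == "oa_onset":
            ledger.add("osteoarthritis", ongoing(t, c.osteoarthritis_annual))
        elif e.kind == "osa_onset":
            ledger.add("sleep_apnea", ongoing(t, c.sleep_apnea_annual))
        elif e.kind in ("factor_update", "discontinuation", "t2d_onset",
                        "background_death", "horizon_end"):
            pass
        else:
            raise KeyError(f"no cost rule for event kind {e.kind!r}")


def accrue_indirect_costs(history: PatientHistory, params: ParameterSet,
                          ledger: CostLedger) -> None:
    if not params.simulation.include_indirect_costs:
        return
    r = params.simulation.discount_rate_costs
    amount = 0.0
    for a, b in _bmi_above_threshold_intervals(
        history, params, params.costs.obesity_bmi_threshold
    ):
        amount += params.costs.indirect_annual * discounted_exposure(a, b, r)
    ledger.add("indirect", amount)


def compute_ledger(history: PatientHistory, params: ParameterSet) -> CostLedger:
    """Full discounted cost ledger for one patient history."""
    ledger = CostLedger()
    accrue_treatment_costs(history, params, ledger)
    accrue_concomitant_costs(history, params, ledger)
    accrue_event_costs(history, params, ledger)
    accrue_indirect_costs(history, params, ledger)
    return ledger
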