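"""Utility paths and discounted QALYs from a simulated patient history.

Baseline utility is a sex-specific linear regression on BMI, evaluated at the
current BMI while it is below baseline (the weight-loss increment) and at the
baseline BMI otherwise.  MI and stroke act multiplicatively on that baseline
(by sex, primary/secondary history, and first vs. subsequent year after the
event; when several apply, the most severe multiplier is used).  All other
conditions (HF, diabetes complications, cancer, osteoarthritis, sleep apnea)
subtract flat decrements from the multiplied value; the result is floored at
zero.  Utility is treated as piecewise-constant between grid/state-change
breakpoints, evaluated at the segment midpoint, and integrated with
continuous discounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ParameterSet
from .economics import discounted_exposure
from .engine import PatientHistory
from .population import PatientProfile
from .risk import HealthState, StateError
from .trajectory import bmi_at, update_grid


@dataclass(frozen=True)
class UtilityTrace:
    breakpoints: np.ndarray      # yr, len = len(utility) + 1
    utility: np.ndarray          # dimensionless, per interval
    qalys_discounted: float
    lys_discounted: float


def baseline_utility(sex: str, bmi: float, params: ParameterSet) -> float:
    """Sex-specific baseline utility at a given BMI, clamped to (0, 1]."""
    if bmi <= 0:
        raise ValueError("bmi must be > 0")
    reg = params.utilities.baseline_regression[sex]
    u = reg.intercept + reg.slope_per_bmi * bmi
    return float(np.clip(u, 1e-6, 1.0))


def _cv_multiplier(
    t: float,
    cv_events: list[tuple[float, str, bool]],
    sex: str,
    baseline_cv_history: bool,
    params: ParameterSet,
) -> float:
    candidates = []
    table = params.utilities.cv_multiplier
    for te, subtype, primary in cv_events:
        if te > t:
            continue
        window = "first_year" if t <= te + 1.0 else "subsequent"
        stratum = "primary" if primary else "secondary"
        for part in subtype.split("_"):
            if part in ("mi", "stroke"):
                pair = table[f"{stratum}_{part}"][sex]
                candidates.append(getattr(pair, window))
    if baseline_cv_history:
        # unspecified pre-existing CV history: primary-MI subsequent-years value
        candidates.append(table["primary_mi"][sex].subsequent)
    return min(candidates, default=1.0)


def utility_at(
    t: float,
    state: HealthState,
    profile: PatientProfile,
    params: ParameterSet,
    cv_events: list[tuple[float, str, bool]] = (),
    current_bmi: float | None = None,
) -> float:
    """Instantaneous utility for an alive patient at time ``t``."""
    if not state.alive:
        raise StateError("utility is undefined for a dead state")
    bmi = current_bmi if current_bmi is not None else state.factors.get("bmi", profile.bmi0)
    bmi_eval = bmi if bmi < profile.bmi0 else profile.bmi0
    base = baseline_utility(profile.sex, bmi_eval, params)
    baseline_cv = "prior_cv_event" in profile.history
    mult = _cv_multiplier(t, list(cv_events), profile.sex, baseline_cv, params)
    u = base * mult
    dec = params.utilities.decrements
    if state.hf:
        u -= dec["hf"]
    for comp in state.diabetes_complications:
        u -= dec[comp]
    if state.cancer_type != "none":
        u -= dec[state.cancer_type]
    if state.osteoarthritis:
        u -= dec["osteoarthritis"]
    if state.sleep_apnea:
        u -= dec["sleep_apnea"]
    return max(u, 0.0)


def _condition_timeline(history: PatientHistory):
    """Yield (time, state, cv_events-so-far) stepping through the history."""
    state = HealthState.from_profile(history.profile)
    cv_events: list[tuple[float, str, bool]] = []
    changes = [(0.0, state.snapshot(), list(cv_events))]
    for e in history.events:
        if e.kind == "cv_event":
            cv_events.append((e.time, e.detail["subtype"], e.detail["primary"]))
        if e.state_after is not None:
            changes.append((e.time, e.state_after, list(cv_events)))
    return changes


def integrate_qalys(
    history: PatientHistory, params: ParameterSet
) -> UtilityTrace:
    """Discounted life years and QALYs over [0, min(death, horizon)]."""
    r = params.simulation.discount_rate_health
    end = history.end_time
    if end <= 0:
        return UtilityTrace(np.array([0.0]), np.array([]), 0.0, 0.0)

    pts = {0.0, end}
    plan = history.plan
    pts |= {min(plan.t_initial_end, end), min(plan.t_attenuated_end, end)}
    if plan.t_discontinue is not None:
        pts |= {min(plan.t_discontinue, end), min(plan.t_regain_end, end)}
    for g in update_grid(history.horizon):
        if g <= end:
            pts.add(float(g))
    for e in history.events:
        if e.time < end:
            pts.add(e.time)
        if e.kind in ("cv_event",) and e.time + 1.0 < end:
            pts.add(e.time + 1.0)  # first-year multiplier window boundary
    breakpoints = np.array(sorted(pts))

    timeline = _condition_timeline(history)
    times = [c[0] for c in timeline]

    utilities = []
    qalys = 0.0
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        mid = 0.5 * (a + b)
        idx = int(np.searchsorted(times, a, side="right") - 1)
        _, state, cv_events = timeline[max(idx, 0)]
        bmi = bmi_at(min(mid, end), history.profile, plan, params)
        u = utility_at(mid, state, history.profile, params, cv_events, current_bmi=bmi)
        utilities.append(u)
        qalys += u * discounted_exposure(float(a), float(b), r)

    lys = discounted_exposure(0.0, end, r)
    return UtilityTrace(breakpoints, np.array(utilities), qalys, lys)
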