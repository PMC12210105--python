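"""The discrete event simulation loop.

Each patient is simulated once per treatment arm over identical baseline
profiles (a perfectly balanced trial).  Hazards are re-evaluated at every
update-grid time from the current trajectory and health state and held
constant in between; candidate event times are re-sampled at every update
(memoryless re-scheduling, distributionally equivalent for piecewise-constant
hazards).  State changes take effect at the instant of the event and hazards
are refreshed immediately.

Randomness is organised as common random numbers: every uniform draw is a
counter-based variate keyed by (master seed, profile id, purpose, grid
segment, occurrence), so the same patient facing the same decision at the
same point of the schedule receives the same draw in every arm, every
scenario and every horizon.  Arm contrasts therefore reflect treatment, not
sampling noise, and runs over nested horizons agree on their shared window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ParameterSet
from .population import PatientProfile
from .risk import (
    DIABETES_COMPLICATIONS,
    HealthState,
    LifeTable,
    assign_cv_event_type,
    cancer_onset_rate,
    diabetes_complication_rates,
    framingham_cvd_10y,
    post_mi_hf_rate,
    ratchet_rate,
    risk10_to_rate,
    secondary_cv_rate,
    t2d_onset_rate,
)
from .trajectory import PhasePlan, build_phase_plan, factor_snapshot, update_grid

#: event processes, each with its own keyed family of uniform draws
PURPOSES = (
    "discontinuation", "primary_cv", "cv_type", "cv_fatal", "secondary_cv",
    "post_mi_hf", "t2d", "dm_foot_ulcer", "dm_amputation", "dm_retinopathy",
    "dm_renal", "cancer_onset", "cancer_type", "cancer_death", "oa", "osa",
    "background",
)
_PURPOSE_ID = {p: i for i, p in enumerate(PURPOSES)}

TERMINAL_KINDS = {"cv_event_fatal", "cancer_death", "background_death", "horizon_end"}


@dataclass(frozen=True)
class EventRecord:
    time: float
    kind: str
    detail: dict = field(default_factory=dict)
    state_after: HealthState | None = None


@dataclass
class PatientHistory:
    """Chronological record of one patient in one arm."""

    profile: PatientProfile
    arm: str
    plan: PhasePlan
    horizon: float
    events: list[EventRecord]
    death_time: float | None

    @property
    def end_time(self) -> float:
        return self.death_time if self.death_time is not None else self.horizon

    def events_of(self, *kinds: str) -> list[EventRecord]:
        return [e for e in self.events if e.kind in kinds]


def sample_discontinuation_time(annual_prob: float, u: float) -> float:
    """Continuous discontinuation time from a constant exponential rate
    matching the annual probability in distribution; infinite when 0."""
    if not 0.0 <= annual_prob < 1.0:
        raise ValueError("annual_prob must lie in [0, 1)")
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie in (0, 1)")
    if annual_prob == 0.0:
        return math.inf
    lam = -math.log1p(-annual_prob)
    return -math.log(u) / lam


class StreamBank:
    """Counter-based uniform variates for one patient.

    ``uniform(purpose, segment)`` hashes (master seed, profile id, purpose,
    segment, occurrence-within-segment) through a seed sequence, so draws are
    reproducible and aligned across arms/scenarios/horizons regardless of how
    many draws other processes consumed earlier (common random numbers).
    """

    def __init__(self, master_seed: int, profile_id: int):
        self._base = (int(master_seed), int(profile_id))
        self._counts: dict[tuple[int, int], int] = {}

    def uniform(self, purpose: str, segment: int) -> float:
        pid = _PURPOSE_ID[purpose]
        key = (pid, segment)
        occ = self._counts.get(key, 0)
        self._counts[key] = occ + 1
        ss = np.random.SeedSequence([*self._base, pid, segment, occ])
        word = int(ss.generate_state(1, dtype=np.uint64)[0])
        return (word + 0.5) / 2.0 ** 64  # open interval (0, 1)


def _active_rates(
    state: HealthState,
    profile: PatientProfile,
    params: ParameterSet,
    life_table: LifeTable,
) -> dict[str, float]:
    rates: dict[str, float] = {}
    if state.prior_primary_cv:
        rates["secondary_cv"] = secondary_cv_rate(state, params)
    else:
        rates["primary_cv"] = risk10_to_rate(
            framingham_cvd_10y(state, profile.sex, profile.smoker, params)
        )
    if state.prior_mi and not state.hf:
        rates["post_mi_hf"] = post_mi_hf_rate(state, params)
    if state.t2d:
        for comp, rate in diabetes_complication_rates(state, params).items():
            if comp not in state.diabetes_complications:
                rates[f"dm_{comp}"] = rate
    else:
        rates["t2d"] = t2d_onset_rate(state, profile.sex, profile.smoker, params)
    if state.cancer_type == "none" and "cancer" not in profile.history:
        rates["cancer_onset"], _ = cancer_onset_rate(
            state, profile.sex, profile.bmi0, params
        )
    elif state.cancer_type != "none":
        rates["cancer_death"] = params.baseline_rates.cancer.excess_mortality[
            state.cancer_type
        ]
    hr = params.risk_coefficients.hazard_ratios_per_bmi_unit
    bmi = state.factors["bmi"]
    if not state.osteoarthritis:
        rates["oa"] = ratchet_rate(
            params.baseline_rates.osteoarthritis, hr["osteoarthritis"], bmi, profile.bmi0
        )
    if not state.sleep_apnea:
        rates["osa"] = ratchet_rate(
            params.baseline_rates.sleep_apnea, hr["sleep_apnea"], bmi, profile.bmi0
        )
    rates["background"] = life_table.rate(state.age, profile.sex)
    return rates


def _pick_cancer_type(dist: dict[str, float], u: float) -> str:
    cum = 0.0
    items = list(dist.items())
    for t, p in items:
        cum += p
        if u < cum:
            return t
    return items[-1][0]


def simulate_patient(
    profile: PatientProfile,
    arm: str,
    params: ParameterSet,
    master_seed: int,
    life_table: LifeTable | None = None,
) -> PatientHistory:
    """Run the event loop for one patient in one arm (see module docstring)."""
    if life_table is None:
        life_table = LifeTable.from_params(params)
    bank = StreamBank(master_seed, profile.id)
    horizon = params.horizon_years(profile.age)
    if horizon <= 0:
        plan = build_phase_plan(arm, None, params)
        return PatientHistory(profile, arm, plan, 0.0,
                              [EventRecord(0.0, "horizon_end")], None)

    t_disc_raw = sample_discontinuation_time(
        params.discontinuation_annual_prob[arm], bank.uniform("discontinuation", 0)
    )
    t_disc = t_disc_raw if t_disc_raw < horizon else None
    plan = build_phase_plan(arm, t_disc, params)

    grid = update_grid(horizon)
    boundaries = sorted(set(float(g) for g in grid[1:]) | ({t_disc} if t_disc else set()))

    state = HealthState.from_profile(profile)
    events: list[EventRecord] = []
    death_time: float | None = None
    fatality = params.risk_coefficients.cv_case_fatality

    def refresh(t: float) -> None:
        state.age = profile.age + t
        state.factors = factor_snapshot(t, profile, plan, params)

    t = 0.0
    b_idx = 0
    eps = 1e-12
    while t < horizon - eps and death_time is None:
        while b_idx < len(boundaries) and boundaries[b_idx] <= t + eps:
            b_idx += 1
        t_next = boundaries[b_idx] if b_idx < len(boundaries) else horizon
        refresh(t)
        seg = int(np.searchsorted(grid, t, side="right") - 1)
        rates = _active_rates(state, profile, params, life_table)
        best_t, best = t_next, None
        for purpose, rate in rates.items():
            if rate <= 0.0:
                continue
            cand = t + -math.log(bank.uniform(purpose, seg)) / rate
            if cand < best_t:
                best_t, best = cand, purpose

        if best is None:
            t = t_next
            if t_disc is not None and abs(t - t_disc) < eps:
                refresh(t)
                events.append(EventRecord(t, "discontinuation",
                                          state_after=state.snapshot()))
            elif t < horizon - eps:
                events.append(EventRecord(t, "factor_update"))
            continue

        t = best_t
        refresh(t)
        seg = int(np.searchsorted(grid, t, side="right") - 1)
        if best == "primary_cv" or best == "secondary_cv":
            is_primary = best == "primary_cv"
            subtype = assign_cv_event_type(is_primary, bank.uniform("cv_type", seg), params)
            fatal = bank.uniform("cv_fatal", seg) < fatality[subtype]
            if fatal:
                death_time = t
                events.append(EventRecord(t, "cv_event_fatal",
                                          {"subtype": subtype, "primary": is_primary},
                                          state.snapshot()))
                break
            state.prior_primary_cv = True
            if "mi" in subtype.split("_"):
                state.prior_mi = True
            if "stroke" in subtype.split("_"):
                state.prior_stroke = True
            if "hf" in subtype.split("_"):
                state.hf = True
            events.append(EventRecord(t, "cv_event",
                                      {"subtype": subtype, "primary": is_primary},
                                      state.snapshot()))
        elif best == "post_mi_hf":
            state.hf = True
            events.append(EventRecord(t, "hf_onset", state_after=state.snapshot()))
        elif best == "t2d":
            state.t2d = True
            events.append(EventRecord(t, "t2d_onset", state_after=state.snapshot()))
        elif best.startswith("dm_"):
            comp = best[3:]
            state.diabetes_complications.add(comp)
            events.append(EventRecord(t, "diabetes_complication",
                                      {"subtype": comp}, state.snapshot()))
        elif best == "cancer_onset":
            _, dist = cancer_onset_rate(state, profile.sex, profile.bmi0, params)
            ctype = _pick_cancer_type(dist, bank.uniform("cancer_type", seg))
            state.cancer_type = ctype
            events.append(EventRecord(t, "cancer_onset", {"type": ctype},
                                      state.snapshot()))
        elif best == "cancer_death":
            death_time = t
            events.append(EventRecord(t, "cancer_death",
                                      {"type": state.cancer_type}, state.snapshot()))
        elif best == "oa":
            state.osteoarthritis = True
            events.append(EventRecord(t, "oa_onset", state_after=state.snapshot()))
        elif best == "osa":
            state.sleep_apnea = True
            events.append(EventRecord(t, "osa_onset", state_after=state.snapshot()))
        elif best == "background":
            death_time = t
            events.append(EventRecord(t, "background_death",
                                      state_after=state.snapshot()))
        else:  # pragma: no cover - defensive
            raise RuntimeError(f"unhandled event purpose {best!r}")

    if death_time is None:
        events.append(EventRecord(horizon, "horizon_end"))
    return PatientHistory(profile, arm, plan, horizon, events, death_time)


def simulate_cohort(
    profiles: list[PatientProfile],
    arms: list[str],
    params: ParameterSet,
    master_seed: int,
) -> dict[str, list[PatientHistory]]:
    """Simulate the identical profile set under every arm with common random
    numbers; fully reproducible given ``master_seed``."""
    if not profiles:
        raise ValueError("need at least one profile")
    if len(arms) < 1:
        raise ValueError("need at least one arm")
    life_table = LifeTable.from_params(params)
    return {
        arm: [
            simulate_patient(p, arm, params, master_seed, life_table)
            for p in profiles
        ]
        for arm in arms
    }
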