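"""Metabolic-factor trajectories through the five treatment phases.

BMI follows a piecewise-linear path: *initial loss* (rapid), *attenuated
loss* (slower, ending at the trial-anchored percent change from baseline),
*maintenance* (treated, drifting upward at the untreated natural-history
rate), *regain* after discontinuation (back to baseline plus the drift the
patient would have accumulated untreated, over a fixed regain duration), and
*natural history* (untreated drift) thereafter.  Discontinuation during a
loss phase truncates it: regain starts from the level attained at that
moment.

The five non-BMI factors (waist circumference, HDL, triglycerides, SBP, FPG)
scale by their own trial percent changes during the loss phases and are
coupled to BMI afterwards: each changes ``factor_per_bmi[factor]`` units per
kg/m2 of BMI change over the same interval.

Between grid updates every quantity changes linearly, so trajectories are
evaluated with an exact piecewise-linear closed form; the update grid (every
6 months for the first 6 years, every 2 years thereafter) governs hazard
re-evaluation, not trajectory resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ARMS, COUPLED_FACTORS, ParameterSet
from .population import PatientProfile


@dataclass(frozen=True)
class PhasePlan:
    """Per-arm timeline of the treatment phases for one patient."""

    arm: str
    t_initial_end: float          # yr, end of initial loss (possibly truncated)
    t_attenuated_end: float       # yr, end of attenuated loss (possibly truncated)
    t_discontinue: float | None   # yr, or None (never discontinues)
    t_regain_end: float | None    # yr, discontinuation + regain duration

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if not 0 < self.t_initial_end <= self.t_attenuated_end:
            raise ValueError("phase boundaries must satisfy 0 < initial <= attenuated")
        if (self.t_discontinue is None) != (self.t_regain_end is None):
            raise ValueError("t_discontinue and t_regain_end must be set together")
        if self.t_discontinue is not None:
            if self.t_discontinue <= 0:
                raise ValueError("t_discontinue must be > 0")
            if self.t_regain_end <= self.t_discontinue:
                raise ValueError("t_regain_end must follow t_discontinue")


def update_grid(horizon: float) -> np.ndarray:
    """Hazard re-evaluation times: every 0.5 yr to year 6, every 2 yr after,
    with the horizon appended if it is not already on the grid."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    first = np.arange(0.0, min(horizon, 6.0) + 1e-9, 0.5)
    times = list(first)
    t = 8.0
    while t <= horizon + 1e-9:
        times.append(t)
        t += 2.0
    if abs(times[-1] - horizon) > 1e-9 and times[-1] < horizon:
        times.append(float(horizon))
    return np.asarray(times)


def build_phase_plan(
    arm: str, t_discontinue: float | None, params: ParameterSet
) -> PhasePlan:
    """Assemble the phase timeline given a (possibly absent) discontinuation
    time.  Discontinuation inside a loss phase truncates the phase; the
    regain phase always lasts ``regain_duration`` years."""
    pd_ = params.phase_durations
    t1, t2 = pd_.initial_loss_end, pd_.attenuated_loss_end
    if t_discontinue is None:
        return PhasePlan(arm, t1, t2, None, None)
    if t_discontinue <= 0:
        raise ValueError("t_discontinue must be > 0 or None")
    return PhasePlan(
        arm,
        min(t1, t_discontinue),
        min(t2, t_discontinue),
        t_discontinue,
        t_discontinue + pd_.regain_duration,
    )


def _loss_level(
    t: float, baseline: float, pct_change: float, params: ParameterSet
) -> float:
    """Level during the (untruncated) loss phases at time t <= attenuated end."""
    pd_ = params.phase_durations
    t1, t2 = pd_.initial_loss_end, pd_.attenuated_loss_end
    share = pd_.initial_share
    total = baseline * pct_change / 100.0
    if t <= t1:
        return baseline + share * total * (t / t1)
    frac = (t - t1) / (t2 - t1)
    return baseline + total * (share + (1.0 - share) * frac)


def bmi_at(
    t: float,
    profile: PatientProfile,
    plan: PhasePlan,
    params: ParameterSet,
    horizon: float | None = None,
) -> float:
    """BMI (kg/m2) at time ``t`` on the patient's piecewise-linear path."""
    if t < 0 or (horizon is not None and t > horizon + 1e-9):
        raise ValueError(f"t={t} outside [0, horizon]")
    baseline = profile.bmi0
    slope = params.nh_bmi_slope[profile.sex]
    pct = params.efficacy[plan.arm]["bmi"]
    d = plan.t_discontinue

    if d is None or t <= d:
        if t <= plan.t_attenuated_end:
            return _loss_level(t, baseline, pct, params)
        # maintenance: hold the achieved loss, drift at the untreated rate
        end_level = _loss_level(plan.t_attenuated_end, baseline, pct, params)
        return end_level + slope * (t - plan.t_attenuated_end)

    t_r = plan.t_regain_end
    if t <= t_r:
        level_d = bmi_at(d, profile, plan, params)
        target = baseline + slope * t_r
        return level_d + (target - level_d) * (t - d) / (t_r - d)
    # natural history: baseline + drift from model entry
    return baseline + slope * t


def factor_at(
    t: float,
    factor: str,
    profile: PatientProfile,
    plan: PhasePlan,
    params: ParameterSet,
    horizon: float | None = None,
) -> float:
    """Level of a non-BMI metabolic factor at time ``t``.

    Loss phases scale by the factor's own trial percent change; afterwards
    the factor moves ``factor_per_bmi[factor]`` units per kg/m2 of BMI change
    over the same interval.  HDL and FPG are floored at configured
    physiologic minima.
    """
    if factor not in COUPLED_FACTORS:
        raise KeyError(f"unknown factor {factor!r}; expected one of {COUPLED_FACTORS}")
    if t < 0 or (horizon is not None and t > horizon + 1e-9):
        raise ValueError(f"t={t} outside [0, horizon]")
    baseline = profile.factor0(factor)
    pct = params.efficacy[plan.arm][factor]
    coupling = params.factor_per_bmi[factor]
    d = plan.t_discontinue
    t_loss_end = plan.t_attenuated_end if d is None else min(plan.t_attenuated_end, d)

    if t <= t_loss_end:
        value = _loss_level(t, baseline, pct, params)
    else:
        anchor = _loss_level(t_loss_end, baseline, pct, params)
        bmi_anchor = bmi_at(t_loss_end, profile, plan, params)
        value = anchor + coupling * (bmi_at(t, profile, plan, params) - bmi_anchor)
    floor = params.simulation.factor_floors.get(factor)
    if floor is not None:
        value = max(value, floor)
    return value


def factor_snapshot(
    t: float, profile: PatientProfile, plan: PhasePlan, params: ParameterSet
) -> dict[str, float]:
    snap = {"bmi": bmi_at(t, profile, plan, params)}
    for f in COUPLED_FACTORS:
        snap[f] = factor_at(t, f, profile, plan, params)
    return snap


def export_trajectory(
    profile: PatientProfile,
    plan: PhasePlan,
    params: ParameterSet,
    horizon: float,
) -> pd.DataFrame:
    """Factor paths sampled on the update grid (for plotting/debugging)."""
    times = update_grid(horizon)
    rows = [
        {"t": float(t), **factor_snapshot(float(t), profile, plan, params)}
        for t in times
    ]
    df = pd.DataFrame(rows)
    df.insert(0, "arm", plan.arm)
    df.insert(0, "id", profile.id)
    return df
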