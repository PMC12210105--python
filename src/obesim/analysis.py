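"""Cohort aggregation, incremental cost-effectiveness, scenarios, DSA, PSA.

Per-arm means are taken over the identical profile set simulated with common
random numbers; ICERs are computed from unrounded mean deltas.  The scenario
registry reproduces the published scenario battery (risk-equation switches,
population subsets, discontinuation extremes, horizons, discount rates,
societal perspective); the deterministic sensitivity analysis perturbs single
leaves to low/high values and orders parameters by ICER range (tornado); the
probabilistic sensitivity analysis re-samples parameters only, reusing the
same profiles and event-stream seeds so that parameter uncertainty is
isolated from Monte-Carlo noise, and summarises draws as a cost-effectiveness
acceptability curve (CEAC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ParameterSet
from .economics import CATEGORIES, CostLedger, compute_ledger
from .engine import PatientHistory, simulate_cohort
from .population import PatientProfile, subset_population
from .qol import UtilityTrace, integrate_qalys

TIME_TO_EVENT_KEYS = (
    "t2d", "primary_mi", "primary_stroke", "secondary_mi", "secondary_stroke",
)


@dataclass(frozen=True)
class ArmResult:
    arm: str
    mean_costs: dict[str, float]          # by category plus "total"
    mean_ly: float
    mean_qaly: float
    mean_time_to: dict[str, float | None]  # conditional on occurrence
    n: int


@dataclass(frozen=True)
class IncrementalResult:
    comparator: tuple[str, str]           # (intervention, reference)
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float | str
    icer_per_ly: float | str


def _first_event_time(history: PatientHistory, key: str) -> float | None:
    if key == "t2d":
        ev = history.events_of("t2d_onset")
        return ev[0].time if ev else None
    stratum, part = key.split("_")
    want_primary = stratum == "primary"
    for e in history.events_of("cv_event", "cv_event_fatal"):
        if e.detail["primary"] == want_primary and part in e.detail["subtype"].split("_"):
            return e.time
    return None


def summarize_arm(
    histories: list[PatientHistory],
    ledgers: list[CostLedger],
    traces: list[UtilityTrace],
) -> ArmResult:
    """Unweighted cohort means; times-to-event conditional on occurrence."""
    if not histories:
        raise ValueError("cannot summarise an empty cohort")
    n = len(histories)
    mean_costs = {
        cat: float(np.mean([led.by_category[cat] for led in ledgers]))
        for cat in CATEGORIES
    }
    mean_costs["total"] = sum(mean_costs.values())
    times: dict[str, float | None] = {}
    for key in TIME_TO_EVENT_KEYS:
        obs = [t for h in histories if (t := _first_event_time(h, key)) is not None]
        times[key] = float(np.mean(obs)) if obs else None
    return ArmResult(
        arm=histories[0].arm,
        mean_costs=mean_costs,
        mean_ly=float(np.mean([tr.lys_discounted for tr in traces])),
        mean_qaly=float(np.mean([tr.qalys_discounted for tr in traces])),
        mean_time_to=times,
        n=n,
    )


def _ratio_or_label(delta_cost: float, delta_effect: float) -> float | str:
    if delta_effect == 0.0:
        return "undefined"
    if delta_cost <= 0.0 and delta_effect > 0.0:
        return "dominant"
    if delta_cost >= 0.0 and delta_effect < 0.0:
        return "dominated"
    return delta_cost / delta_effect


def incremental(a: ArmResult, b: ArmResult) -> IncrementalResult:
    """Pairwise deltas a - b with ICERs from unrounded means."""
    if a.n != b.n:
        raise ValueError("arm results must come from the same profile set")
    dc = a.mean_costs["total"] - b.mean_costs["total"]
    dly = a.mean_ly - b.mean_ly
    dq = a.mean_qaly - b.mean_qaly
    return IncrementalResult(
        comparator=(a.arm, b.arm),
        delta_cost=dc,
        delta_ly=dly,
        delta_qaly=dq,
        icer_per_qaly=_ratio_or_label(dc, dq),
        icer_per_ly=_ratio_or_label(dc, dly),
    )


def evaluate_arms(
    profiles: list[PatientProfile],
    arms: list[str],
    params: ParameterSet,
    master_seed: int,
) -> dict[str, ArmResult]:
    """Simulate, cost and integrate the cohort; one ArmResult per arm."""
    cohort = simulate_cohort(profiles, arms, params, master_seed)
    out = {}
    for arm, histories in cohort.items():
        ledgers = [compute_ledger(h, params) for h in histories]
        traces = [integrate_qalys(h, params) for h in histories]
        out[arm] = summarize_arm(histories, ledgers, traces)
    return out


def arm_results_frame(results: dict[str, ArmResult]) -> pd.DataFrame:
    rows = []
    for arm, r in results.items():
        row = {"arm": arm, "n": r.n, "ly": r.mean_ly, "qaly": r.mean_qaly}
        row.update({f"cost_{k}": v for k, v in r.mean_costs.items()})
        row.update({f"time_to_{k}": v for k, v in r.mean_time_to.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenarios


def _zero_cancer_oa_osa_overrides(params: ParameterSet) -> dict:
    ov: dict = {
        "baseline_rates.osteoarthritis": 0.0,
        "baseline_rates.sleep_apnea": 0.0,
        "costs.osteoarthritis_annual": 0.0,
        "costs.sleep_apnea_annual": 0.0,
        "costs.cancer_terminal": 0.0,
        "utilities.decrements.osteoarthritis": 0.0,
        "utilities.decrements.sleep_apnea": 0.0,
    }
    for i, _ in enumerate(params.baseline_rates.cancer.age_bands):
        ov[f"baseline_rates.cancer.age_bands.{i}.rate"] = 0.0
    for ctype in params.costs.cancer:
        ov[f"costs.cancer.{ctype}.first_year"] = 0.0
        ov[f"costs.cancer.{ctype}.subsequent_annual"] = 0.0
        ov[f"utilities.decrements.{ctype}"] = 0.0
    return ov


def scenario_names() -> list[str]:
    return [
        "cvd_t2d_only", "diabetes_san_antonio", "diabetes_framingham",
        "societal", "prediabetes", "obesity_class_3", "pessimistic_disc",
        "optimistic_disc", "horizon_10y", "horizon_20y", "discount_2pct",
        "all_smokers", "all_nonsmokers",
    ]


def _scenario_bundle(name: str, params: ParameterSet):
    """(parameter overrides, population filter or None) for a scenario."""
    overrides: dict = {}
    pop_filter: str | None = None
    if name == "cvd_t2d_only":
        overrides = _zero_cancer_oa_osa_overrides(params)
    elif name == "diabetes_san_antonio":
        overrides = {"risk_coefficients.t2d_equation_default": "san_antonio"}
    elif name == "diabetes_framingham":
        overrides = {"risk_coefficients.t2d_equation_default": "framingham"}
    elif name == "societal":
        overrides = {"simulation.include_indirect_costs": True}
    elif name in ("prediabetes", "obesity_class_3", "all_smokers", "all_nonsmokers"):
        pop_filter = name
    elif name == "pessimistic_disc":
        overrides = {f"discontinuation_annual_prob.{a}": 0.50
                     for a in ("tzp5", "tzp10", "tzp15")}
    elif name == "optimistic_disc":
        overrides = {f"discontinuation_annual_prob.{a}": 0.0
                     for a in ("tzp5", "tzp10", "tzp15")}
    elif name == "horizon_10y":
        overrides = {"simulation.horizon": 10.0}
    elif name == "horizon_20y":
        overrides = {"simulation.horizon": 20.0}
    elif name == "discount_2pct":
        overrides = {"simulation.discount_rate_costs": 0.02,
                     "simulation.discount_rate_health": 0.02}
    else:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {scenario_names()}"
        )
    return overrides, pop_filter


def run_scenario(
    name: str,
    base_params: ParameterSet,
    profiles: list[PatientProfile],
    master_seed: int,
    comparator: tuple[str, str] = ("tzp10", "lsm"),
) -> IncrementalResult:
    """Apply the named override bundle and re-run the cohort with the same
    master seed; results compare the intervention arm with the reference."""
    overrides, pop_filter = _scenario_bundle(name, base_params)
    params = base_params.with_overrides(overrides) if overrides else base_params
    pop = profiles
    if pop_filter is not None:
        pop = subset_population(
            profiles, pop_filter,
            tuple(base_params.population.prediabetes_fpg_band),
        )
        if not pop:
            raise ValueError(f"scenario {name!r} produced an empty population")
    results = evaluate_arms(pop, list(comparator), params, master_seed)
    return incremental(results[comparator[0]], results[comparator[1]])


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis (tornado)


def run_dsa(
    param_list: list[dict],
    base_params: ParameterSet,
    profiles: list[PatientProfile],
    master_seed: int,
    comparator: tuple[str, str] = ("tzp10", "lsm"),
) -> pd.DataFrame:
    """One-way sensitivity: each entry names a dotted leaf with explicit
    ``low``/``high`` values or a relative band (default +/-20%); rows are
    sorted by ICER range (tornado order).  The same master seed is used
    throughout."""
    rows = []
    for entry in param_list:
        key = entry["key"]
        base_value = base_params.get_dotted(key)
        rel = entry.get("rel", 0.20)
        low = entry.get("low", base_value * (1 - rel))
        high = entry.get("high", base_value * (1 + rel))
        icers = {}
        for bound, value in (("low", low), ("high", high)):
            params = base_params.with_overrides({key: value})
            results = evaluate_arms(profiles, list(comparator), params, master_seed)
            inc = incremental(results[comparator[0]], results[comparator[1]])
            icers[bound] = (
                inc.icer_per_qaly if isinstance(inc.icer_per_qaly, float) else math.nan
            )
        rng = (
            abs(icers["high"] - icers["low"])
            if all(math.isfinite(v) for v in icers.values())
            else 0.0
        )
        rows.append({
            "key": key, "base": base_value, "low": low, "high": high,
            "icer_low": icers["low"], "icer_high": icers["high"], "range": rng,
        })
    df = pd.DataFrame(rows).sort_values("range", ascending=False, kind="stable")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _sample_distribution(spec: dict, rng: np.random.Generator) -> float:
    family = spec["family"]
    if family == "normal":
        return float(rng.normal(spec["mean"], spec["sd"]))
    if family == "lognormal":
        mean, sd = spec["mean"], spec["sd"]
        sigma2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2
        return float(rng.lognormal(mu, math.sqrt(sigma2)))
    if family == "beta":
        return float(rng.beta(spec["alpha"], spec["beta"]))
    if family == "gamma":
        return float(rng.gamma(spec["shape"], spec["scale"]))
    raise ValueError(f"unknown distribution family {family!r}")


def default_psa_distributions(params: ParameterSet) -> dict[str, dict]:
    """Documented conventions: costs ~ gamma with 20% CV; discontinuation
    probabilities ~ beta with effective sample size 100; efficacy percent
    changes ~ normal with SD 10% of the point estimate's magnitude."""
    dists: dict[str, dict] = {}
    for key in ("costs.tirzepatide_annual", "costs.lsm_year1",
                "costs.lsm_subsequent", "costs.hf_annual_followup",
                "costs.mi_hospitalization", "costs.stroke_hospitalization"):
        mean = params.get_dotted(key)
        dists[key] = {"family": "gamma", "shape": 25.0, "scale": mean / 25.0}
    for arm in ("tzp5", "tzp10", "tzp15", "lsm"):
        p = params.discontinuation_annual_prob[arm]
        dists[f"discontinuation_annual_prob.{arm}"] = {
            "family": "beta", "alpha": p * 100.0, "beta": (1 - p) * 100.0,
        }
        pct = params.efficacy[arm]["bmi"]
        dists[f"efficacy.{arm}.bmi"] = {
            "family": "normal", "mean": pct, "sd": abs(pct) * 0.10,
        }
    return dists


def run_psa(
    n_draws: int,
    distributions: dict[str, dict],
    base_params: ParameterSet,
    profiles: list[PatientProfile],
    seed: int,
    comparator: tuple[str, str] = ("tzp10", "lsm"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint parameter resampling; returns (draws table, CEAC table).

    Each draw perturbs parameters only — profiles and event-stream seeds are
    identical across draws — and records the incremental cost and QALY of the
    comparator pair.  CEAC(lambda) is the fraction of draws with positive net
    monetary benefit at willingness-to-pay lambda.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for draw in range(n_draws):
        overrides = {k: _sample_distribution(spec, rng)
                     for k, spec in distributions.items()}
        params = base_params.with_overrides(overrides)
        results = evaluate_arms(profiles, list(comparator), params, seed)
        inc = incremental(results[comparator[0]], results[comparator[1]])
        rows.append({"draw": draw, "delta_cost": inc.delta_cost,
                     "delta_qaly": inc.delta_qaly, "delta_ly": inc.delta_ly})
    draws = pd.DataFrame(rows)
    ceac_rows = []
    for wtp in base_params.wtp_grid:
        nmb = wtp * draws["delta_qaly"] - draws["delta_cost"]
        ceac_rows.append({"wtp": wtp, "prob_cost_effective": float((nmb > 0).mean())})
    return draws, pd.DataFrame(ceac_rows)
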