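"""Parameter registry: typed model parameters with provenance.

Every number the simulation consumes lives in one YAML document (the shipped
``data/default_config.yaml`` or a user file) and is validated into a
:class:`ParameterSet`.  Scenario, deterministic and probabilistic sensitivity
analyses perturb single leaves through flat dotted-key overrides
(``costs.tirzepatide_annual=11000``), so no parameter is buried in code.

Each leaf carries a provenance tag — ``paper_table`` (printed in the source
publication), ``cited_ref`` (transcribed from a cited publication) or
``placeholder`` (supplementary-only values shipped as labelled plausible
defaults) — resolved by longest dotted-prefix match against the
``provenance:`` block.
"""

from __future__ import annotations

import copy
import importlib.resources
import logging
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

ARMS = ("tzp5", "tzp10", "tzp15", "lsm")
TZP_ARMS = ("tzp5", "tzp10", "tzp15")
FACTORS = ("bmi", "wc", "hdl", "tg", "sbp", "fpg")
COUPLED_FACTORS = ("wc", "hdl", "tg", "sbp", "fpg")
CANCER_TYPES = ("colon", "kidney", "esophageal", "pancreatic", "endometrial", "breast")

Provenance = Literal["paper_table", "cited_ref", "placeholder"]


class _Frozen(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhaseDurations(_Frozen):
    initial_loss_end: float = Field(gt=0)
    attenuated_loss_end: float = Field(gt=0)
    regain_duration: float = Field(gt=0)
    initial_share: float = Field(gt=0, le=1)

    @model_validator(mode="after")
    def _ordered(self) -> "PhaseDurations":
        if not self.initial_loss_end < self.attenuated_loss_end:
            raise ValueError("initial_loss_end must precede attenuated_loss_end")
        return self


class CancerCost(_Frozen):
    first_year: float = Field(ge=0)
    subsequent_annual: float = Field(ge=0)


class Costs(_Frozen):
    tirzepatide_annual: float = Field(ge=0)
    tirzepatide_package: float = Field(ge=0)
    lsm_year1: float = Field(ge=0)
    lsm_subsequent: float = Field(ge=0)
    lisinopril_annual: float = Field(ge=0)
    metformin_glimepiride_annual: float = Field(ge=0)
    simvastatin_annual: float = Field(ge=0)
    mi_hospitalization: float = Field(ge=0)
    mi_first_3mo: float = Field(ge=0)
    mi_annual_followup: float = Field(ge=0)
    stroke_hospitalization: float = Field(ge=0)
    stroke_first_3mo: float = Field(ge=0)
    stroke_annual_followup: float = Field(ge=0)
    hf_annual_followup: float = Field(ge=0)
    cv_death: float = Field(ge=0)
    foot_ulcer: float = Field(ge=0)
    amputation: float = Field(ge=0)
    retinopathy_annual: float = Field(ge=0)
    renal_annual: float = Field(ge=0)
    osteoarthritis_annual: float = Field(ge=0)
    sleep_apnea_annual: float = Field(ge=0)
    cancer: dict[str, CancerCost]
    cancer_terminal: float = Field(ge=0)
    indirect_annual: float = Field(ge=0)
    obesity_bmi_threshold: float = Field(gt=0)

    @field_validator("cancer")
    @classmethod
    def _all_types(cls, v: dict[str, CancerCost]) -> dict[str, CancerCost]:
        missing = set(CANCER_TYPES) - set(v)
        if missing:
            raise ValueError(f"cancer cost table missing types: {sorted(missing)}")
        return v


class BaselineRegression(_Frozen):
    intercept: float
    slope_per_bmi: float


class CVMultiplierPair(_Frozen):
    first_year: float = Field(gt=0, le=1)
    subsequent: float = Field(gt=0, le=1)


class Utilities(_Frozen):
    baseline_regression: dict[str, BaselineRegression]
    cv_multiplier: dict[str, dict[str, CVMultiplierPair]]
    decrements: dict[str, float]

    @field_validator("decrements")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for k, d in v.items():
            if d < 0:
                raise ValueError(f"utility decrement {k} must be stored as a magnitude >= 0")
        return v


class FraminghamSexCoefficients(_Frozen):
    ln_age: float
    ln_total_chol: float
    ln_hdl: float
    ln_sbp_untreated: float
    ln_sbp_treated: float
    smoker: float
    diabetes: float
    s0_10: float = Field(gt=0, lt=1)
    mean_lp: float


class SecondaryCV(_Frozen):
    base_annual_rate: float = Field(ge=0)
    ref_age: float
    log_hr_per_year_age: float


class T2DEquation(_Frozen):
    base_annual_rate: float = Field(ge=0)
    coefficients: dict[str, float]
    reference: dict[str, float]


class RiskCoefficients(_Frozen):
    framingham_cvd: dict[str, FraminghamSexCoefficients]
    assumed_ldl: float = Field(gt=0)
    secondary_cv: SecondaryCV
    cv_event_type_split: dict[str, dict[str, float]]
    cv_case_fatality: dict[str, float]
    post_mi_hf_annual_rate: float = Field(ge=0)
    t2d_equations: dict[str, T2DEquation]
    t2d_equation_default: str
    hazard_ratios_per_bmi_unit: dict[str, float]
    cv_death_share: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _checks(self) -> "RiskCoefficients":
        for stratum, split in self.cv_event_type_split.items():
            total = sum(split.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cv_event_type_split[{stratum}] sums to {total}, not 1")
            if any(p < 0 for p in split.values()):
                raise ValueError("cv_event_type_split probabilities must be >= 0")
        for hf_cat in ("hf", "mi_hf", "stroke_hf"):
            if self.cv_event_type_split.get("secondary", {}).get(hf_cat, 0.0) > 0:
                raise ValueError("HF-containing categories are primary-stratum only")
        for k, p in self.cv_case_fatality.items():
            if not 0 <= p <= 1:
                raise ValueError(f"cv_case_fatality[{k}] outside [0, 1]")
        if self.t2d_equation_default not in self.t2d_equations:
            raise ValueError(f"unknown default T2D equation {self.t2d_equation_default!r}")
        for k, hr in self.hazard_ratios_per_bmi_unit.items():
            if hr <= 0:
                raise ValueError(f"hazard ratio {k} must be > 0")
        return self


class CancerAgeBand(_Frozen):
    lower: float
    upper: float
    rate: float = Field(ge=0)


class CancerRates(_Frozen):
    age_bands: list[CancerAgeBand]
    type_distribution: dict[str, dict[str, float]]
    excess_mortality: dict[str, float]

    @model_validator(mode="after")
    def _checks(self) -> "CancerRates":
        for sex, dist in self.type_distribution.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cancer type distribution for {sex} sums to {total}")
            if sex == "male" and any(t in dist and dist[t] > 0 for t in ("endometrial", "breast")):
                raise ValueError("endometrial/breast cancer mass must be 0 for males")
        for t, r in self.excess_mortality.items():
            if r < 0:
                raise ValueError(f"cancer excess mortality {t} must be >= 0")
        return self


class BaselineRates(_Frozen):
    osteoarthritis: float = Field(ge=0)
    sleep_apnea: float = Field(ge=0)
    diabetes_complications: dict[str, float]
    cancer: CancerRates

    @field_validator("diabetes_complications")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for k, r in v.items():
            if r < 0:
                raise ValueError(f"diabetes complication rate {k} must be >= 0")
        return v


class MarginalSpec(_Frozen):
    mean: float = Field(gt=0)
    sd: float = Field(ge=0)
    min: float | None = None
    max: float | None = None


class PopulationConfig(_Frozen):
    n: int = Field(gt=0)
    seed: int = Field(ge=0)
    marginals: dict[str, Any]
    correlation: list[list[float]]
    complication_prevalence: dict[str, float]
    prediabetes_fpg_band: tuple[float, float]

    @model_validator(mode="after")
    def _checks(self) -> "PopulationConfig":
        for k, p in self.complication_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"complication prevalence {k} outside [0, 1]")
        for k in ("p_female", "p_smoker"):
            p = self.marginals.get(k)
            if p is None or not 0 <= p <= 1:
                raise ValueError(f"marginals.{k} must be a probability")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
            raise ValueError("correlation must be a square matrix")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-9:
            raise ValueError("correlation matrix must be positive semi-definite")
        lo, hi = self.prediabetes_fpg_band
        if not lo < hi:
            raise ValueError("prediabetes band must be (low, high) with low < high")
        return self


class SimulationConfig(_Frozen):
    horizon: float | Literal["lifetime"]
    max_age: float = Field(gt=0)
    discount_rate_costs: float = Field(ge=0, lt=1)
    discount_rate_health: float = Field(ge=0, lt=1)
    include_indirect_costs: bool = False
    factor_floors: dict[str, float]
    metformin_fpg_threshold: float = Field(gt=0)
    lisinopril_sbp_threshold: float = Field(gt=0)

    @field_validator("horizon")
    @classmethod
    def _horizon(cls, v):
        if isinstance(v, (int, float)) and v <= 0:
            raise ValueError("horizon must be > 0 or 'lifetime'")
        return v


class ParameterSet(_Frozen):
    """Validated, provenance-tagged model parameters (see module docstring)."""

    efficacy: dict[str, dict[str, float]]
    discontinuation_annual_prob: dict[str, float]
    nh_bmi_slope: dict[str, float]
    factor_per_bmi: dict[str, float]
    phase_durations: PhaseDurations
    costs: Costs
    utilities: Utilities
    risk_coefficients: RiskCoefficients
    baseline_rates: BaselineRates
    population: PopulationConfig
    simulation: SimulationConfig
    wtp_grid: list[float]
    life_table_file: str
    provenance: dict[str, Provenance] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _checks(self) -> "ParameterSet":
        if set(self.efficacy) != set(ARMS):
            raise ValueError(f"efficacy must cover exactly arms {ARMS}")
        for arm, table in self.efficacy.items():
            if set(table) != set(FACTORS):
                raise ValueError(f"efficacy[{arm}] must cover exactly factors {FACTORS}")
        if set(self.discontinuation_annual_prob) != set(ARMS):
            raise ValueError(f"discontinuation_annual_prob must cover arms {ARMS}")
        for arm, p in self.discontinuation_annual_prob.items():
            if not 0 <= p < 1:
                raise ValueError(
                    f"discontinuation_annual_prob[{arm}]={p} outside [0, 1)"
                )
        if set(self.nh_bmi_slope) != {"male", "female"}:
            raise ValueError("nh_bmi_slope needs exactly male and female entries")
        missing = set(COUPLED_FACTORS) - set(self.factor_per_bmi)
        if missing:
            raise ValueError(f"factor_per_bmi missing factors: {sorted(missing)}")
        if any(w < 0 for w in self.wtp_grid):
            raise ValueError("wtp_grid values must be >= 0")
        return self

    # -- convenience -------------------------------------------------------

    def horizon_years(self, age0: float) -> float:
        """Simulation horizon for a patient entering at ``age0``."""
        remaining = self.simulation.max_age - age0
        if self.simulation.horizon == "lifetime":
            return max(remaining, 0.0)
        return max(min(float(self.simulation.horizon), remaining), 0.0)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)

    def with_overrides(self, overrides: dict[str, Any]) -> "ParameterSet":
        """Return a new ParameterSet with flat dotted-key leaves replaced."""
        raw = self.model_dump(mode="python")
        for key, value in overrides.items():
            _set_dotted(raw, key, value)
        return ParameterSet.model_validate(raw)

    def get_dotted(self, key: str) -> Any:
        node: Any = self.model_dump(mode="python")
        for part in key.split("."):
            if isinstance(node, list):
                node = node[int(part)]
            else:
                if part not in node:
                    raise KeyError(f"unknown parameter key {key!r}")
                node = node[part]
        return node


def _set_dotted(tree: dict[str, Any], key: str, value: Any) -> None:
    parts = key.split(".")
    node: Any = tree
    for part in parts[:-1]:
        if isinstance(node, list):
            node = node[int(part)]
        elif part in node:
            node = node[part]
        else:
            raise KeyError(f"unknown parameter key {key!r} (at {part!r})")
    last = parts[-1]
    if isinstance(node, list):
        node[int(last)] = value
    else:
        if last not in node:
            raise KeyError(f"unknown parameter key {key!r} (leaf {last!r})")
        node[last] = value


def default_config_text() -> str:
    return (
        importlib.resources.files("obesim.data")
        .joinpath("default_config.yaml")
        .read_text()
    )


def load_parameters(
    path: str | None = None, overrides: dict[str, Any] | None = None
) -> ParameterSet:
    """Load and validate a parameter file (the shipped default when ``path``
    is None).  Blocks omitted from a user file are filled from the defaults;
    placeholder-tagged leaves trigger a logged warning listing them."""
    defaults = yaml.safe_load(default_config_text())
    if path is None:
        raw = defaults
    else:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        raw = _deep_merge(defaults, user)
    params = ParameterSet.model_validate(raw)
    if overrides:
        params = params.with_overrides(overrides)
    placeholders = [
        key
        for key, _, tag in _leaves_with_provenance(params)
        if tag == "placeholder"
    ]
    if placeholders:
        logger.warning(
            "%d parameters use placeholder defaults (supplementary-only "
            "sources): %s", len(placeholders), ", ".join(sorted(set(
                p.split(".")[0] for p in placeholders))),
        )
    return params


def _deep_merge(base: dict[str, Any], override: dict[str, Any]) -> dict[str, Any]:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if k in out and isinstance(out[k], dict) and isinstance(v, dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _flatten(node: Any, prefix: str = "") -> list[tuple[str, Any]]:
    if isinstance(node, dict):
        items: list[tuple[str, Any]] = []
        for k, v in node.items():
            items.extend(_flatten(v, f"{prefix}{k}."))
        return items
    if isinstance(node, list):
        items = []
        for i, v in enumerate(node):
            items.extend(_flatten(v, f"{prefix}{i}."))
        return items
    return [(prefix[:-1], node)]


def _leaves_with_provenance(params: ParameterSet):
    raw = params.model_dump(mode="json")
    prov_map = raw.pop("provenance", {})
    for key, value in _flatten(raw):
        tag = "placeholder"
        best = -1
        for prefix, t in prov_map.items():
            if (key == prefix or key.startswith(prefix + ".")) and len(prefix) > best:
                best = len(prefix)
                tag = t
        yield key, value, tag


def parameter_provenance_report(params: ParameterSet) -> pd.DataFrame:
    """One row per leaf parameter: (key, value, provenance).

    The provenance-count summary is attached as ``df.attrs['counts']``.
    """
    rows = list(_leaves_with_provenance(params))
    df = pd.DataFrame(rows, columns=["key", "value", "provenance"])
    df.attrs["counts"] = df["provenance"].value_counts().to_dict()
    return df
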