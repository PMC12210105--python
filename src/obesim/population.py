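"""Synthetic baseline patient profiles.

Generates survey-like joint distributions of age, sex, smoking, BMI, waist
circumference, HDL, triglycerides, SBP and fasting plasma glucose via a
Gaussian copula on log scale, plus baseline complication flags, then applies
the anti-obesity-medication eligibility filter: BMI >= 30, or BMI >= 27 with
at least one obesity-related complication; baseline type 2 diabetes excluded.

Users with real survey extracts can bypass the generator entirely and load a
profile table from CSV (`read_profiles`); sampling weights are carried but
default to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ParameterSet

logger = logging.getLogger(__name__)

COMPLICATION_FLAGS = (
    "prior_cv_event",
    "hf",
    "hypertension",
    "dyslipidemia",
    "t2d",
    "osteoarthritis",
    "sleep_apnea",
    "cancer",
)
#: complications that confer eligibility at BMI 27-30 (T2D is an exclusion)
ELIGIBILITY_COMPLICATIONS = tuple(f for f in COMPLICATION_FLAGS if f != "t2d")

_COPULA_FIELDS = ("age", "bmi", "wc", "hdl", "tg", "sbp", "fpg")

PROFILE_COLUMNS = [
    "id", "sex", "age", "smoker", "bmi0", "wc0", "hdl0", "tg0", "sbp0",
    "fpg0", *COMPLICATION_FLAGS, "weight",
]


@dataclass(frozen=True)
class PatientProfile:
    """One simulated individual's baseline state."""

    id: int
    sex: str                # "male" | "female"
    age: float              # yr
    smoker: bool
    bmi0: float             # kg/m2
    wc0: float              # cm
    hdl0: float             # mg/dL
    tg0: float              # mg/dL
    sbp0: float             # mm Hg
    fpg0: float             # mg/dL
    history: frozenset[str] = field(default_factory=frozenset)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.age < 18:
            raise ValueError("profiles must be adults (age >= 18)")
        for name in ("bmi0", "wc0", "hdl0", "tg0", "sbp0", "fpg0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        unknown = set(self.history) - set(COMPLICATION_FLAGS)
        if unknown:
            raise ValueError(f"unknown history flags: {sorted(unknown)}")

    def factor0(self, factor: str) -> float:
        return {
            "bmi": self.bmi0, "wc": self.wc0, "hdl": self.hdl0,
            "tg": self.tg0, "sbp": self.sbp0, "fpg": self.fpg0,
        }[factor]


@dataclass(frozen=True)
class PopulationSpec:
    """Generator settings: marginal moments, copula correlation over
    (age, bmi, wc, hdl, tg, sbp, fpg) and complication prevalences."""

    n: int
    seed: int
    marginals: dict
    correlation: np.ndarray
    complication_prevalence: dict

    def __post_init__(self) -> None:
        corr = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "correlation", corr)
        if corr.shape != (len(_COPULA_FIELDS),) * 2:
            raise ValueError(
                f"correlation must be {len(_COPULA_FIELDS)}x{len(_COPULA_FIELDS)} "
                f"over {_COPULA_FIELDS}"
            )
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-9:
            raise ValueError("correlation matrix is not positive semi-definite")
        for k, p in self.complication_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {k}={p} outside [0, 1]")

    @classmethod
    def from_params(cls, params: ParameterSet, n: int | None = None,
                    seed: int | None = None) -> "PopulationSpec":
        pop = params.population
        return cls(
            n=n if n is not None else pop.n,
            seed=seed if seed is not None else pop.seed,
            marginals=dict(pop.marginals),
            correlation=np.asarray(pop.correlation, dtype=float),
            complication_prevalence=dict(pop.complication_prevalence),
        )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given natural-scale mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_profiles(spec: PopulationSpec) -> list[PatientProfile]:
    """Draw ``spec.n`` baseline profiles (reproducible given ``spec.seed``).

    Continuous factors are coupled by a Gaussian copula: a correlated
    standard normal vector is mapped through per-field lognormal marginals
    (positivity preserved).  Age is clamped to its configured [min, max].
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    chol = np.linalg.cholesky(
        spec.correlation + 1e-12 * np.eye(len(_COPULA_FIELDS))
    )
    z = rng.standard_normal((n, len(_COPULA_FIELDS))) @ chol.T
    values: dict[str, np.ndarray] = {}
    for j, name in enumerate(_COPULA_FIELDS):
        m = spec.marginals[name]
        mu, sigma = _lognormal_params(float(m["mean"]), float(m["sd"]))
        x = np.exp(mu + sigma * z[:, j])
        if m.get("min") is not None:
            x = np.maximum(x, float(m["min"]))
        if m.get("max") is not None:
            x = np.minimum(x, float(m["max"]))
        values[name] = x

    female = rng.random(n) < float(spec.marginals["p_female"])
    smoker = rng.random(n) < float(spec.marginals["p_smoker"])
    flags = {
        f: rng.random(n) < float(spec.complication_prevalence.get(f, 0.0))
        for f in COMPLICATION_FLAGS
    }

    profiles = []
    for i in range(n):
        history = frozenset(f for f in COMPLICATION_FLAGS if flags[f][i])
        profiles.append(PatientProfile(
            id=i,
            sex="female" if female[i] else "male",
            age=float(values["age"][i]),
            smoker=bool(smoker[i]),
            bmi0=float(values["bmi"][i]),
            wc0=float(values["wc"][i]),
            hdl0=float(values["hdl"][i]),
            tg0=float(values["tg"][i]),
            sbp0=float(values["sbp"][i]),
            fpg0=float(values["fpg"][i]),
            history=history,
        ))
    return profiles


def is_eligible(profile: PatientProfile) -> bool:
    if "t2d" in profile.history:
        return False
    if profile.bmi0 >= 30.0:
        return True
    has_complication = any(f in profile.history for f in ELIGIBILITY_COMPLICATIONS)
    return profile.bmi0 >= 27.0 and has_complication


def apply_eligibility(profiles: list[PatientProfile]) -> list[PatientProfile]:
    """Keep profiles meeting the BMI/complication criterion, excluding
    baseline T2D; order preserved."""
    kept = [p for p in profiles if is_eligible(p)]
    logger.info("eligibility filter kept %d of %d profiles", len(kept), len(profiles))
    return kept


def subset_population(
    profiles: list[PatientProfile],
    criterion: str,
    prediabetes_band: tuple[float, float] = (100.0, 126.0),
) -> list[PatientProfile]:
    """Scenario population filters.

    ``prediabetes``: FPG within [band_low, band_high) mg/dL;
    ``obesity_class_3``: BMI >= 40; ``all_smokers`` / ``all_nonsmokers``:
    set the smoking flag on the whole cohort (cohort size preserved).
    """
    lo, hi = prediabetes_band
    if criterion == "prediabetes":
        out = [p for p in profiles if lo <= p.fpg0 < hi]
    elif criterion == "obesity_class_3":
        out = [p for p in profiles if p.bmi0 >= 40.0]
    elif criterion == "all_smokers":
        out = [replace(p, smoker=True) for p in profiles]
    elif criterion == "all_nonsmokers":
        out = [replace(p, smoker=False) for p in profiles]
    else:
        raise KeyError(
            f"unknown subset criterion {criterion!r}; expected one of "
            "prediabetes, obesity_class_3, all_smokers, all_nonsmokers"
        )
    if not out:
        logger.warning("subset %r produced an empty population", criterion)
    return out


def profiles_to_frame(profiles: list[PatientProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "id": p.id, "sex": p.sex, "age": p.age, "smoker": p.smoker,
            "bmi0": p.bmi0, "wc0": p.wc0, "hdl0": p.hdl0, "tg0": p.tg0,
            "sbp0": p.sbp0, "fpg0": p.fpg0, "weight": p.weight,
        }
        for f in COMPLICATION_FLAGS:
            row[f] = f in p.history
        rows.append(row)
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def frame_to_profiles(df: pd.DataFrame) -> list[PatientProfile]:
    profiles = []
    for _, r in df.iterrows():
        history = frozenset(f for f in COMPLICATION_FLAGS if bool(r[f]))
        profiles.append(PatientProfile(
            id=int(r["id"]), sex=str(r["sex"]), age=float(r["age"]),
            smoker=bool(r["smoker"]), bmi0=float(r["bmi0"]), wc0=float(r["wc0"]),
            hdl0=float(r["hdl0"]), tg0=float(r["tg0"]), sbp0=float(r["sbp0"]),
            fpg0=float(r["fpg0"]), history=history, weight=float(r["weight"]),
        ))
    return profiles


def write_profiles(profiles: list[PatientProfile], path: str) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path: str) -> list[PatientProfile]:
    return frame_to_profiles(pd.read_csv(path))


def generate_eligible_cohort(
    params: ParameterSet, n: int | None = None, seed: int | None = None
) -> list[PatientProfile]:
    """Sample profiles and filter to eligibility, topping up until ``n``
    eligible profiles are available (ids renumbered 0..n-1)."""
    spec = PopulationSpec.from_params(params, n=n, seed=seed)
    target = spec.n
    eligible: list[PatientProfile] = []
    draw_seed = spec.seed
    batch = max(target, 64)
    while len(eligible) < target:
        got = apply_eligibility(
            sample_profiles(PopulationSpec(
                n=batch, seed=draw_seed, marginals=spec.marginals,
                correlation=spec.correlation,
                complication_prevalence=spec.complication_prevalence,
            ))
        )
        eligible.extend(got)
        draw_seed += 1
    eligible = eligible[:target]
    return [replace(p, id=i) for i, p in enumerate(eligible)]
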