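# obesim

Individual-level discrete event simulation (DES) of the lifetime
cost-effectiveness of tirzepatide (5, 10 or 15 mg) versus lifestyle
modification (LSM) for adults with obesity or overweight, from a US payer
perspective.

`obesim` is aimed at health-economics and outcomes researchers who want a
transparent, scriptable, fully parameterised reimplementation of this class
of obesity microsimulation: every input lives in one provenance-tagged YAML
configuration, every analysis (base case, scenarios, one-way deterministic
sensitivity, probabilistic sensitivity) is a library call or a CLI
subcommand, and all randomness is reproducible common-random-number
simulation.

## The model

Each simulated patient carries a baseline profile (age, sex, smoking, BMI,
waist circumference, HDL, triglycerides, SBP, fasting plasma glucose, and
complication history), drawn from a survey-like synthetic generator and
filtered to anti-obesity-medication eligibility (BMI ≥ 30, or BMI ≥ 27 with
at least one obesity-related complication; baseline type 2 diabetes
excluded). The identical profile set receives each treatment arm — a
perfectly balanced trial.

BMI follows five treatment phases: *initial loss* → *attenuated loss*
(reaching the 72-week trial percent change from baseline, e.g. −22.5 % for
tirzepatide 15 mg, −2.4 % for LSM) → *maintenance* (drifting upward at the
untreated natural-history rate, 0.1447 / 0.1747 kg·m⁻²·yr⁻¹ for men /
women) → *regain* after all-cause discontinuation (annual probabilities
11.2 / 12.2 / 10.6 / 19.9 % for TZP 5/10/15 mg and LSM), returning over
3 years to baseline plus untreated drift → *natural history*. The other five
metabolic factors scale by their own trial percent changes during the loss
phases and track BMI linearly afterwards.

Metabolic state drives time-varying hazards, re-evaluated on the model's
update grid (every 6 months for 6 years, then every 2 years): primary
cardiovascular events via the Framingham 10-year general-CVD equation
(converted to a rate as λ = −ln(1 − p₁₀)/10), secondary CV events, post-MI
heart failure, T2D onset (REGARDS-style equation, with San Antonio and
Framingham alternates), diabetes complications, six obesity-linked cancers,
and osteoarthritis / sleep apnea with BMI-*ratcheted* hazards
(λ = λ₀·HR^max(0, BMI−BMI₀)); background mortality comes from a life table
with the CV-death share removed. Costs (2023 USD) and utilities
(multiplicative MI/stroke effects, additive decrements, a BMI-linked
baseline regression) accrue in continuous time with 3 %/yr discounting, and
arms are compared as

ICER = ΔCost / ΔQALY (or ΔCost / ΔLY), computed from unrounded means.

Input values printed in the source cost-effectiveness study are shipped
verbatim; supplementary-only inputs ship as clearly tagged placeholders (see
`docs/methods.md`), so headline absolute numbers are indicative, while the
arithmetic, trajectory, sampling and accounting layers are exact.

## Worked example

```python
from obesim import (load_parameters, generate_eligible_cohort,
                    evaluate_arms, incremental)

params = load_parameters()                                   # shipped defaults
profiles = generate_eligible_cohort(params, n=1000, seed=2024)
results = evaluate_arms(profiles, ["tzp5", "tzp10", "tzp15", "lsm"],
                        params, master_seed=2024)
for arm in ("tzp5", "tzp10", "tzp15"):
    inc = incremental(results[arm], results["lsm"])
    print(f"{arm} vs lsm: dC=${inc.delta_cost:,.0f} dLY={inc.delta_ly:.2f} "
          f"dQALY={inc.delta_qaly:.2f} ICER=${inc.icer_per_qaly:,.0f}/QALY")
```

prints (1000 patients per arm, lifetime horizon, ~16 s on one core):

```
tzp5 vs lsm: dC=$72,848 dLY=0.13 dQALY=0.31 ICER=$235,061/QALY
tzp10 vs lsm: dC=$66,151 dLY=0.06 dQALY=0.31 ICER=$214,621/QALY
tzp15 vs lsm: dC=$75,834 dLY=0.15 dQALY=0.41 ICER=$186,804/QALY
```

Each tirzepatide dose buys extra quality-adjusted survival (driven by
delayed T2D and CV onset plus the weight-loss utility increment) at extra
cost (driven by drug price, partly offset by avoided complications). With
the shipped placeholder inputs the QALY gains are smaller and the ICERs
correspondingly higher than the published study's ($125k–$146k per QALY);
the incremental costs land within a few percent of the published values.

Scenario, DSA and PSA drivers mirror the published analysis battery:

```python
from obesim import run_scenario, run_dsa, run_psa
inc = run_scenario("discount_2pct", params, profiles, 2024)
tornado = run_dsa([{"key": "costs.tirzepatide_annual"}], params, profiles, 2024)
```

The same operations are exposed on the command line:

```bash
obesim generate-profiles --n 1000 --seed 2024 --out profiles.csv
obesim simulate --profiles profiles.csv --seed 2024 --out-dir out/
obesim scenario --name obesity_class_3 --profiles profiles.csv --seed 2024
obesim dsa --spec dsa.yaml --profiles profiles.csv --seed 2024
obesim psa --n 200 --profiles profiles.csv --seed 2024 --out-dir out/
obesim provenance            # parameter provenance report
```

Any leaf parameter can be overridden with repeated
`--set key=value` flags (e.g. `--set simulation.horizon=10`).

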