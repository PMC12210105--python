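# Methods

This note documents the model implemented by `obesim`: its structure and
assumptions, the parameters that matter, what the synthetic population
emulates, the numerical conventions, and the design choices made where the
design was genuinely open. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model structure

`obesim` is an individual-level discrete event simulation. A patient enters
with a baseline profile, is assigned to one arm (tirzepatide 5, 10 or 15 mg,
or lifestyle modification), and is tracked until death or the horizon
(default: lifetime, capped at age 100). The model advances between sampled
event times rather than fixed cycles; persistent conditions ("patient has
heart failure") are flags that events switch on, which keeps comorbidity
tracking simple compared with mutually exclusive state-based designs.

Six metabolic factors are tracked: BMI, waist circumference, HDL,
triglycerides, SBP and fasting plasma glucose. They are deterministic
functions of time given the arm, the baseline profile and the (sampled)
discontinuation time; all stochasticity lives in event occurrence.

### Treatment phases

BMI is piecewise linear through five phases:

1. **Initial loss** (default 0–24 weeks): rapid loss; by the phase end a
   configurable share (default 70 %) of the arm's total percent change is
   reached.
2. **Attenuated loss** (default 24–72 weeks): the trial-anchored total
   percent change from baseline is reached exactly at 72 weeks.
3. **Maintenance**: the achieved level drifts upward at the untreated
   natural-history slope (0.1447 / 0.1747 kg·m⁻²·yr⁻¹, men / women) until
   discontinuation.
4. **Regain**: from the level at discontinuation, linearly up to
   *baseline + slope × t* over a fixed 3 years, so the patient rejoins the
   untreated trajectory exactly (regain closure, enforced by test).
   Discontinuing during a loss phase truncates it; regain starts from the
   level attained at that instant.
5. **Natural history**: *baseline + slope × t* thereafter.

The 24/72-week phase boundaries are anchored to the efficacy trial's
endpoint; the 70 % initial-phase share is a placeholder (the source's
supplementary figure is schematic). Whether the LSM arm shares the
tirzepatide phase timing is not stated in the source; we assume it does.

The five non-BMI factors scale by their own trial percent changes during the
loss phases, then change by `factor_per_bmi[factor]` units per kg/m² of BMI
change (maintenance, regain and natural history). The coupling coefficients
are supplementary-only and ship as placeholders with cross-sectional
literature magnitudes (waist 2.3 cm, HDL −0.5 mg/dL, TG 4 mg/dL, SBP
0.8 mm Hg, FPG 0.8 mg/dL per BMI unit). HDL and FPG are floored at
physiologic minima (10 / 60 mg/dL) to guard extreme sensitivity-analysis
draws. Percent changes are scale-invariant, so FPG efficacy applies
identically in mg/dL and mmol/L; conversions happen only at I/O boundaries.

### Update grid and hazard evaluation

Factor levels are interpolated exactly (closed-form piecewise-linear), but
hazards are re-evaluated only at update-grid times — every 6 months for the
first 6 years, every 2 years thereafter, horizon appended — and held
constant in between (piecewise-exponential sampling). A state-changing event
refreshes all hazards at the instant it occurs rather than at the next grid
point. Candidate event times are re-sampled at every re-evaluation
(memoryless re-scheduling), which is distributionally equivalent for
piecewise-constant hazards; whether the original implementation re-samples
or carries forward residual times is not stated, and this choice is the
package's own.

### Risks

* **Primary CV events** — Framingham 10-year general-CVD Cox equation,
  coefficients transcribed from its source publication. The 10-year risk is
  converted to a constant annual rate λ = −ln(1 − p₁₀)/10 and re-evaluated
  at each grid time with current covariates (the source states no conversion
  rule; piecewise-constant re-evaluation is the standard DES treatment).
  Total cholesterol is not tracked and is reconstructed as
  HDL + TG/5 + assumed LDL (inverse Friedewald; assumed LDL 115 mg/dL,
  placeholder). "Treated SBP" means SBP above the antihypertensive trigger
  (130 mm Hg). Diabetes raises CV risk solely through the equation's
  diabetes indicator.
* **Event typing** — at a CV event the type (MI, stroke, HF, MI+HF,
  stroke+HF) is drawn from a primary/secondary-stratified split;
  HF-containing types occur only as primary events. The split is
  supplementary-only; placeholder values are used. Each type carries a
  placeholder case-fatality probability; fatal events end the simulation.
* **Secondary CV events** — for patients with CV history, a configured
  annual rate with a log-linear age multiplier (the source trial's
  functional form is supplementary-only; placeholder).
* **Post-MI heart failure** — constant annual rate after MI until death
  (placeholder magnitude).
* **T2D onset** — an annual incidence rate at a reference covariate vector,
  scaled log-linearly in FPG, BMI, age, TG, HDL, SBP, smoking and sex. Three
  switchable equations (REGARDS default; San Antonio and Framingham
  alternates) ship as placeholders preserving the published ordering — the
  default is the most conservative (lowest incidence).
* **Diabetes complications** — constant incidence of foot ulcer, amputation,
  retinopathy and renal disease once T2D is present; independent, may
  co-occur, each at most once.
* **Cancer** — six obesity-linked cancers (sex-appropriate top four:
  colon/kidney/esophageal/pancreatic for men, breast/endometrial/colon/
  kidney for women), with age-band onset rates and per-type excess mortality
  added while the cancer is active (synthetic placeholder magnitudes in the
  registry style of the source). At most one cancer per lifetime. Cancer
  mortality is *not* removed from the life table, reproducing the source's
  acknowledged potential double counting.
* **Osteoarthritis and sleep apnea** — ratchet hazards
  λ₀ · HR^max(0, BMI − BMI₀): the hazard scales up with BMI above baseline
  and never falls below its baseline value.
* **Background mortality** — a life table by age and sex, multiplied by
  (1 − CV-death share) since CV deaths are modelled explicitly, clamped at
  the final row. The shipped table (`life_table_synthetic.csv`) is a
  synthetic Gompertz table calibrated to round adult US all-cause
  magnitudes; users with access to official life tables can substitute a CSV
  with the same columns.

Simultaneous candidate events are resolved by minimum sampled time; exact
ties (measure zero) fall to the iteration order death > CV > T2D > cancer >
OA > sleep apnea.

### Costs

All costs are 2023 USD; there is no inflation engine or currency conversion.
Ongoing costs accrue continuously and are discounted with
∫(1+r)^(−t) dt per segment; one-time costs are discounted at the event time.
Defaults: tirzepatide $13,826/yr while on treatment (the $1060/package price
is carried as an independent parameter; annual cost governs accrual); LSM
program $1570 in year 1, $1515 after; concomitant lisinopril $14/yr while
SBP > 130 mm Hg (strict; stops if SBP falls back), simvastatin $23/yr
lifelong after any CV event or HF, metformin+glimepiride $1087/yr lifelong
once T2D or FPG > 126 mg/dL (the threshold is read from the tabulated
">126 mg/dL"; the body text's ">26 mg/dL" is treated as a typographical
error). MI/stroke: acute hospitalization plus a first-3-months lump at event
time, then a long-term annual follow-up beginning 0.25 yr post-event until
death/horizon. HF: annual follow-up from onset. CV death: one-time cost.
Ulcer/amputation: one-time; retinopathy/renal, OA and sleep apnea: annual
until death/horizon. Cancer: per-type first-year vs. subsequent-year
management (the source also stratifies by age and sex; the placeholder
defaults collapse those strata) plus terminal care at cancer death. The
societal-perspective scenario adds a placeholder $4000/yr indirect
(productivity) cost while BMI ≥ 30, computed on exact threshold-crossing
intervals of the piecewise-linear BMI path. LSM program costs stop at LSM
discontinuation (not stated in the source; assumed).

Patients entering with baseline HF, OA or sleep apnea accrue the
corresponding management costs from entry. An unspecified baseline CV event
triggers the statin and secondary-event risk but no follow-up cost stream
(the event type is unknown).

### Utilities

Baseline utility is a sex-specific linear regression on BMI (placeholder
coefficients ≈ 0.90 at BMI 35, −0.004 per BMI unit), clamped to (0, 1].
While current BMI is below baseline the regression is evaluated at current
BMI (the weight-loss increment); at or above baseline it is evaluated at
baseline BMI — regained weight above baseline carries no extra penalty,
mirroring the asymmetric evidence base. MI and stroke act multiplicatively
(by sex, primary/secondary stratum, first vs. subsequent year in continuous
time from the event); when several multipliers apply the most severe
(lowest) is used rather than compounding, because the secondary-event
multipliers already encode prior history. An unspecified baseline CV history
uses the primary-MI subsequent-years multiplier. All other conditions
subtract flat decrements from the multiplied value; the result is floored at
0. Utility is piecewise-constant between grid/state-change/first-year-window
breakpoints, evaluated at the segment midpoint (exact for the
affine-in-time segments that dominate), and integrated with continuous
discounting at 3 %/yr. QALYs never exceed discounted life years.

## Synthetic population

The generator emulates a national-survey-like joint distribution: a Gaussian
copula on log scale over (age, BMI, waist, HDL, TG, SBP, FPG) with
configured marginal means/SDs and a positive-semidefinite correlation matrix
(BMI–waist 0.85, BMI–HDL −0.25, age–SBP 0.35, …), Bernoulli sex/smoking, and
independent complication-prevalence flags. Profiles are filtered to
anti-obesity-medication eligibility with baseline T2D excluded, and topped
up so exactly *n* eligible profiles result. Sampling weights default to 1
and are carried for users importing real survey extracts.

What the generator does **not** emulate: conditional complication
prevalences by BMI class or age, measurement error, survey design effects,
or the source study's exact survey cycles (supplementary-only). Passing
tests therefore demonstrate correctness of the machinery on a realistic
synthetic population, not calibration to any specific survey extract.
Prediabetes is defined as FPG 100–125 mg/dL (ADA convention; config-exposed)
— the source does not define it.

## Randomness and reproducibility

Every uniform draw is a counter-based variate keyed by (master seed, profile
id, purpose, grid segment, occurrence), where "purpose" is one of 17 event
processes. The same patient facing the same decision at the same point of
the schedule therefore receives the same draw in every arm, scenario and
horizon (common random numbers), so arm contrasts reflect treatment rather
than sampling noise, nested horizons agree on their shared window, and
reruns are bitwise identical. Discontinuation is sampled once per patient as
a continuous exponential time with rate −ln(1 − annual probability), which
honours the annual probability in distribution (verified at n = 10⁵).

## Analyses

* **Base case**: 1000 patients per arm, lifetime horizon, 3 %/yr
  discounting; each dose compared pairwise with LSM (a fully incremental
  frontier across doses is available but not the default).
* **Scenarios** (same master seed as base): CVD+T2D only (cancer/OA/sleep
  apnea hazards, costs and decrements disabled), San Antonio / Framingham
  T2D equations, societal perspective, prediabetes-only and class-III-only
  populations, 50 %/yr and 0 %/yr tirzepatide discontinuation, 10- and
  20-year horizons, 2 % discounting, all-smoker / all-nonsmoker cohorts
  (flags set on the whole cohort, preserving n).
* **DSA**: one leaf at a time to low/high (95 % CI where supplied, else
  ±20 %), ICER range sorted (tornado), fixed seed.
* **PSA**: parameters re-sampled jointly (gamma for costs, beta for
  probabilities, normal/lognormal otherwise — conventions, since the
  source's PSA protocol is supplementary-only) with profiles and event
  streams held fixed, isolating parameter uncertainty from Monte-Carlo
  noise; summarised as a CEAC over the willingness-to-pay grid.

## Numerical conventions and problem sizes

Tolerances: CV-type splits must sum to 1 within 1e-9; ledger additivity is
verified to 1e-6; exact worked-example checks use 1e-9. ICERs are computed
from unrounded means and labelled ("dominant", "dominated", "undefined")
instead of divided when signs or zero denominators demand it. The test suite
uses cohorts of 8–300 patients and Monte-Carlo sizes of 5·10⁴–10⁵ draws for
distributional checks; the acceptance script uses 10⁵ discontinuation draws.
A 1000-patient, four-arm lifetime base case runs in well under a minute on
one core.

## Known limitations

* Supplementary-only inputs are placeholders (provenance-tagged, with
  recipes in the config comments): factor–BMI couplings, CV event-type
  split, case fatality, secondary-CV and post-MI-HF rates, T2D equation
  coefficients, cancer incidence/mortality/costs, diabetes-complication
  rates, OA/OSA rates and hazard ratios, baseline-utility regression,
  indirect costs, and the life table. Headline absolute results shift with
  them; the trajectory, sampling, accounting and comparison layers do not.
* No adverse-event modelling beyond all-cause discontinuation, no
  dose-titration pharmacokinetics, no payer-mix or net-price machinery, no
  value-of-information analysis.
* Risk equations developed in general populations are applied to an
  obesity-only population; treatment effects on complications are mediated
  entirely through metabolic factors.
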