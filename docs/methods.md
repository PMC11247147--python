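# Methods

## Model overview

`ckdsim` is a discrete-time, patient-level Monte Carlo microsimulation of
chronic kidney disease (CKD) burden. For one country it draws a closed
virtual cohort whose marginal distributions match a validated input bundle,
then advances every individual through one-year cycles from 2022 to 2027.
National results are obtained by rescaling virtual counts to the national
population; cross-country statistics are population-weighted rollups.

An individual's state is (age, sex, eGFR, urine albumin:creatinine ratio,
KDIGO G/A stage, CKD and diagnosis flags, type 2 diabetes, hypertension,
per-outcome cardiovascular history, KRT modality, vital status). CKD is
present iff eGFR < 60 mL/min/1.73 m² (stages G3a–G5) or albuminuria
≥ 30 mg/g in G1–G2. The KDIGO heat map assigns each (G, A) cell a
low/moderate/high/very-high risk category; the bundle's grid maps each
category to relative risks for heart failure, myocardial infarction, stroke
and all-cause death, with the low category as the reference (rr = 1).

## Annual cycle

Within a simulated year the sub-steps run in a fixed, documented order
(the order itself is a modelling choice; outcome updates within a year are
conditionally independent given the individual's state at the relevant
sub-step):

1. **Ageing** (+1 year; reporting bands 0–17, 18–34, 35–64, ≥65).
2. **Progression.** Individuals with CKD and not on KRT lose eGFR at the
   annual slope of their subtype (combinations of type 2 diabetes,
   hypertension, prior cardiovascular event), floored at 0; individuals
   below the G5 threshold remain G5 until KRT or death. Albuminuria moves
   by an optional annual A-stage transition matrix (default: stay).
   Individuals without CKD do not drift; onset is governed entirely by the
   explicit incidence rates, which keeps the incidence calibratable.
3. **CKD onset.** CKD-free adults convert with the age/sex-specific annual
   probability; incident cases enter at a bundle-supplied onset-stage
   distribution (default 50/50 G2·A2 / G3a·A1) with eGFR and ACR drawn
   uniformly in the cell.
4. **Comorbidity incidence** (optional; default 0 — prevalence is then
   fixed at baseline).
5. **Diagnosis.** Undiagnosed prevalent cases are diagnosed with the
   G-stage-specific annual probability; diagnosis is absorbing. The same
   per-stage table supplies the baseline diagnosed fraction at synthesis —
   a single "diagnosis rate per stage" concept drives both.
6. **Cardiovascular events.** First events of each type are drawn with
   probability min(1, base(age band, sex) × rr(category, outcome)); the
   relative risk applies only to individuals with CKD. Event history feeds
   the progression subtype from the *next* year onward (state at the start
   of the progression sub-step).
7. **KRT.** CKD patients below the eGFR initiation threshold and not yet on
   KRT initiate with the access probability; the modality is drawn from the
   bundle shares (haemodialysis / peritoneal dialysis / transplant), then
   evolves by an annual modality-transition matrix. Patients on KRT stop
   slope progression; transplant recipients keep a Tx-specific mortality
   multiplier (default 1). "No KRT" never recurs after initiation.
8. **Mortality.** All-cause death with probability min(1, base(age band,
   sex) × rr(category, death) × Tx multiplier). Death is absorbing; the
   dead are never updated again.

CKD itself is treated as absorbing: a case whose ACR transitions back below
30 mg/g retains the CKD flag (progressive-disease assumption; negative
slopes make regression across the G threshold impossible anyway).

The cohort is closed — no births, migration, or annual entry of
18-year-olds; minors synthesized at baseline carry no CKD state and age
into eligibility. This matches the fixed-cohort design in which a constant
virtual population is rescaled to the national population each year.

## Random numbers

Every sub-step of every year draws a uniform per individual slot from a
dedicated stream keyed by (master seed, year, sub-step), with slot *i*
permanently owned by individual *i*. Results are therefore independent of
iteration order, byte-reproducible given the seed, and scenario comparisons
with equal seeds share random numbers (common random numbers). That is what
makes the diagnosis-rate sensitivity monotone draw-by-draw: the same
uniform is compared against a scaled threshold in every scenario.

## Virtual-population synthesis

Sex and age band come from the joint pyramid (ages uniform within band;
the open ≥65 band samples 65–90). Adults draw a stage cell — "none" or one
of the 18 (G, A) cells — from the distribution conditional on band and sex,
then a concrete eGFR and ACR uniformly within the cell: G1 [90, 120),
G2 [60, 90), …, G5 [1, 15); A1 [0, 30), A2 [30, 300], A3 (300, 3000].
"None" samples eGFR on [60, 120) and ACR below 30. Uniform-within-cell is
the weakest assumption consistent with stage-level inputs. Comorbidities
are drawn independently of stage given CKD status, because baseline tables
report only CKD-conditional prevalence.

## eGFR equations

Both the 2009 and the 2021 race-free CKD-EPI creatinine equations are
implemented and selected per bundle (default 2021), reflecting that source
data vintage differs by country. Stage boundaries are closed at the lower
G bound (eGFR 60 → G2, 45 → G3a) and A2 is closed at both ends
([30, 300] mg/g); the boundary convention is fixed here because input
sources rarely state one.

## Calibration

KRT prevalence targets come from an ordinary least-squares line through
historical (year, prevalent count) registry datapoints evaluated at the
target year (log-linear optionally, for exponential trends; the regression
family in source studies is typically unstated, so linear is the default
and both are exact on their respective ideal inputs). A scaling knob
(KRT access, CKD incidence or diagnosis rate) is then found by bisection on
a fixed-seed, reduced-size simulation — the simulated summary is a
deterministic monotone function of the multiplier, so bisection converges
and a bracket that does not straddle the target is an error, not a silent
clamp. Note that cumulative quantities can saturate in the knob (repeated
annual access draws eventually treat nearly everyone eligible); calibration
targets should be chosen on a horizon over which the knob is identifiable,
e.g. first-year initiations for access.

## Aggregation conventions

* Prevalence is reported per 100,000 (national population for CKD counts;
  CKD population for complication prevalence).
* Percent change 2022→2027 is reported to one decimal; internal arithmetic
  is unrounded.
* Cumulative incidence is the sum of the six annual incident counts,
  baseline year included.
* Cross-country weighted means weight each country by its CKD population
  (diagnosed + undiagnosed) in the target year — with the packaged country
  tables this convention reproduces the published cardiovascular weighted
  means to within 0.1%.
* The diagnosis-rate sensitivity scales every stage's rate multiplicatively
  by 1 ± 10% (capped at 1, caps logged) under common random numbers. The
  alternative reading — shifting a single pooled rate — is not implemented.
* Rollups require all 31 countries/regions; the UAE enters through its
  Emirati population only.

## Synthetic data

The generator emulates the statistical structure of published baseline
tables: national population size, sex split, four reporting age bands,
stage-specific CKD prevalence, diagnosed fraction, and comorbidity
prevalence in the CKD population. Profiles pin the ≥65 share at the
extremes observed across modelled countries (3.6% "large_young", 28.9%
"small_aged"); age-band CKD prevalences rise steeply with age (e.g. 5% /
12% / 30% across adult bands in the aged profile), G-stage mixtures put the
mode at G3a, and default diagnosis rates rise from 5% (G1) to 80% (G5) per
year. Default eGFR slopes (−1 to −3.5 mL/min/1.73 m²/year by subtype) and
KDIGO relative risks (up to 4× for heart failure, 3.5× for death in the
very-high category) are representative of published CKD cohort analyses.
Scalar ground truths are recorded in bundle metadata for recovery tests.

What the generator does **not** emulate: real countries' correlated input
structure (e.g. stage-specific comorbidity gradients), secular trends in
incidence or mortality, within-country heterogeneity, and any actual
registry values. Passing tests therefore demonstrate internal correctness
of the machinery (marginal recovery, conservation, absorbing states, known
relative-risk recovery), not agreement with any real country's epidemiology.

## Problem sizes and numerical choices

Cohorts of 10⁵ individuals give per-100k Monte Carlo errors of a few
hundred on prevalences near 10%, adequate for the property checks; the
scale-stability test compares 10⁵ against 10⁶ within combined binomial
error. The engine is vectorised (a 10⁵ × 6-year run takes well under a
second on one core), so the full published scale of 2 × 10⁷ individuals
per country is a matter of memory and patience, not design. Probabilities
are always capped at 1 after relative-risk multiplication; distribution
rows must sum to 1 within 10⁻⁹; stage cells are sampled half-open to match
the closed-lower-bound staging convention.

## Known limitations

* Albuminuria dynamics default to "stay" — a per-stage transition matrix
  must be supplied for A-stage progression, because no ACR slope is part of
  the input set.
* All-cause mortality only; no cause-specific decomposition.
* No within-year time structure: events in the same year are drawn
  independently given the start-of-step state.
* Incident CKD enters only through the explicit onset rates; eGFR of
  CKD-free individuals does not drift with age.
* The printed-table rollups inherit the rounding of the published per-100k
  integers; recomputed country extremes can differ from published unrounded
  ones by a few tenths of a percentage point.
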