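# ckdsim

Patient-level Monte Carlo microsimulation of chronic kidney disease (CKD)
burden, for epidemiologists and health-policy modellers who need
country-level projections of CKD prevalence, diagnosis status, kidney
replacement therapy (KRT), cardiovascular complications and mortality.

CKD is staged on two axes: kidney function (eGFR bands G1–G5, with G3
split a/b; CKD at eGFR < 60 mL/min/1.73 m²) and albuminuria (A1–A3; CKD at
uACR ≥ 30 mg/g even with preserved eGFR). `ckdsim` synthesizes a virtual
cohort matching a country's demographic pyramid and joint (G × A) stage
distribution, then advances each individual through annual cycles
2022–2027: eGFR declines by subtype-specific slopes, albuminuria
transitions, incident CKD arises, undiagnosed cases are diagnosed at
stage-specific rates, cardiovascular events (heart failure, myocardial
infarction, stroke) and all-cause death are drawn with probability
min(1, p_base(age, sex) · rr(KDIGO category, outcome)), and patients
reaching the eGFR threshold initiate KRT subject to an access probability.
Virtual counts are rescaled to the national population; cross-country
statistics are weighted rollups.

eGFR comes from the CKD-EPI creatinine equation (2009 or 2021 race-free,
per country), e.g. for the 2009 version:

    eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age · 1.018[F]

with κ = 0.7/0.9 and α = −0.329/−0.411 for females/males.

The package ships CSV transcriptions of the published 31-country summary
tables (national populations, diagnosed/undiagnosed CKD prevalence per
100,000 by stage and year, cardiovascular complication prevalence), and a
synthetic-data module that generates fully validated country input bundles
with known ground truth, so the whole pipeline is testable offline.

## Worked example

```python
>>> import ckdsim
>>> ckdsim.egfr_ckd_epi(1.1, 68, "F", 2021)
54.7326866233198
>>> ckdsim.stage_from_measures(52.6, 120)
StagePair(G='G3a', A='A2', is_ckd=True)
```

eGFR 54.7 with uACR 120 mg/g is stage G3a/A2 — CKD in the KDIGO "high"
risk category. Projecting a synthetic aged-population country (5.8 M
people, 28.9% over 65):

```python
>>> from ckdsim.synthetic_data import generate_bundle
>>> bundle = generate_bundle("small_aged", seed=3)
>>> cohort, outputs = ckdsim.run_projection(bundle, 100_000, seed=3)
>>> f = ckdsim.outputs_to_frame(outputs)
>>> f[["n_alive_end", "deaths", "diagnosed_total", "undiagnosed_total"]]
      n_alive_end  deaths  diagnosed_total  undiagnosed_total
year
2022        97931    2069             3773               9708
2023        95988    1943             4772               8307
2024        94021    1967             5527               7207
2025        92152    1869             6026               6336
2026        90343    1809             6472               5604
2027        88470    1873             6751               4999
```

Of 100,000 virtual individuals, ~13.8% have CKD at baseline but only 3,773
are diagnosed in 2022; annual stage-specific diagnosis converts prevalent
undiagnosed cases over time while mortality (~2% per year in this aged
population) removes others. Scaling by `scale_to_national` converts these
counts to the 5.8 M national population.

The cross-country rollup over the packaged tables:

```
$ ckdsim verify-tables
{
  "total_ckd_cases_2027_millions": 436.6,
  "total_ckd_cases_pct_change": 5.8,
  "undiagnosed_share_2027_pct": 80.2,
  "undiagnosed_share_min": {"Romania": 67.4},
  "undiagnosed_share_max": {"China": 87.4},
  "cv_weighted_means_per_100k": {
    "heart_failure": 8859,
    "myocardial_infarction": 10244,
    "stroke": 7797
  }
}
```

436.6 million people across the 31 countries/regions are projected to have
CKD in 2027 (up 5.8% from 2022), 80.2% of them undiagnosed; per 100,000
CKD patients, the population-weighted cumulative cardiovascular burden by
2027 is 8,859 heart-failure, 10,244 myocardial-infarction and 7,797 stroke
cases.

Other CLI entry points: `ckdsim stage` (stage a CSV of creatinine/age/sex/
ACR rows), `ckdsim project` (run a bundle), `ckdsim make-fixtures` (write
the synthetic profile bundles and table fixtures to a directory).

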