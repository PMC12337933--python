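# rxadherence

Long-term medication adherence and drug-utilization patterns for new users
of antihypertensive monotherapy, computed from raw pharmacy dispensing
records.

Pharmacoepidemiologists studying hypertension management need, from nothing
more than dispensing rows (patient, date, ATC code, days of supply), the
whole analytic chain: a new-user inception cohort with washout and
exclusion rules; proportion-of-days-covered (PDC) adherence by treatment
year; classification of continuation, discontinuation, switch and add-on;
clustering of categorical risk profiles; penalized-regression prediction of
high adherence; and a survival analysis of the time until a patient first
reaches high adherence. `rxadherence` implements each step as a tested
library module, wires them into one reproducible pipeline, and — because
real dispensing databases are proprietary — ships a synthetic-data
generator with planted ground truth so every stage can be validated.

## The statistics at the core

* **Adherence.** Year-k PDC = (covered days in `[360(k−1), 360k)`)/360,
  with carryover of early refills; overall PDC divides by the follow-up
  length; high adherence is PDC ≥ 0.8. Year windows cut by censoring are
  flagged not-evaluable instead of being diluted.
* **Patterns.** Discontinuation = supply gap > 180 days (dated at supply
  exhaustion); switch = another class or fixed-dose combination within 180
  days after discontinuation; add-on = another class strictly inside
  ongoing coverage before discontinuation; continuation = none of these.
* **Clustering.** Gower distance over categorical risk factors (fraction
  of differing variables), partition-around-medoids with exact search for
  small problems, K chosen by average silhouette width.
* **Prediction.** Ridge / LASSO / elastic-net logistic regression
  (glmnet-style λ grid, stratified 7:3 split, 10-fold CV deviance);
  variables with any dummy surviving LASSO at λ_1SE enter an unpenalized
  logistic model reported with odds ratios, Hosmer–Lemeshow calibration and
  Nagelkerke R².
* **Survival.** Event = first 180-day window with PDC ≥ 0.8 (censor at
  1080 days); Kaplan–Meier curves of remaining in low adherence; Cox
  hazard ratios vs beta-blockers, crude and with stabilized multinomial
  IPW, with and without piecewise time-dependent exposure effects;
  time-dependent AUC, Harrell's C, Nagelkerke R².

## Worked example

The numbered scripts under `analysis/` run the chain on a 2000-patient
synthetic cohort (seed 7) and write their tables under `results/analysis/`:

```bash
python analysis/01_simulate.py
python analysis/02_build_cohort.py
python analysis/03_adherence.py
...
python analysis/07_survival.py
```

`03_adherence.py` prints the adherence-rate trend over treatment years:

```
year     n  mean_pdc  high_rate_pct
1     1316     0.911         80.547
2     1026     0.892         81.676
...
10     518     0.948         98.456
high-adherence rate moves from 80.5% (year 1) to 98.5% (year 10)
```

Each year-k row uses only patients persisting beyond 360·k days, so the
rising rate reflects selective persistence of adherent patients — the
qualitative signature this design is built to expose. `06_prediction.py`
fits the prediction model; on this cohort the LASSO group rule keeps (among
others) diabetes (OR 2.13), asthma/COPD (OR 1.87) and psycholeptics
(OR 0.43), matching the planted positive/negative effects, with holdout AUC
0.620 and Hosmer–Lemeshow p = 0.56 (no misfit). `07_survival.py` reports
stabilized weights with mean 1.00 and IPW-adjusted hazard ratios of high
adherence per class vs beta-blockers: 1.17 (ACEI), 1.16 (ARB), 1.19 (CCB),
1.29 (thiazide). The default generator plants no exposure effect on
adherence, so these hover near 1; the thiazide interval (1.04–1.59) grazes
significance purely by sampling noise, a useful reminder of the multiplicity
involved in four simultaneous contrasts.

The same chain is available as one command:

```bash
rxadherence all --out results/run --seed 7 --synthetic
```

or programmatically via `rxadherence.pipeline.run_pipeline(PipelineConfig(...))`.
To analyse real data, point `PipelineConfig` at dispensing and patient CSVs
(`patient_id, dispense_date, atc_code, days_supply` / `patient_id,
birth_date, sex`) and set `synthetic: false`.

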