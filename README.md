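# adcoi — cost of illness of atopic dermatitis in Romania

`adcoi` is a tested, reusable implementation of a national cost-of-illness
(COI) pipeline for atopic dermatitis (AD) in Romania, reference year 2022.
It is written for health economists and epidemiologists who want to audit,
re-run, or adapt a severity-stratified burden estimate that mixes bottom-up
survey costing with top-down national statistics.

## What it computes

Starting from (a) patient/caregiver survey tables — self-rated severity,
employment, three annual out-of-pocket cost categories, missed work/school
days, EQ-5D-5L state and EQ-VAS — and (b) a national-inputs file (GBD 2021
crude counts, hospital discharges, unit costs), the pipeline produces:

1. **Severity stratification.** National cases per stratum
   `N_s = N · c_s / n`, where `c_s` is the integer survey count for
   severity `s` out of `n` respondents and `N` the GBD crude count for the
   segment (adult = 20+ years, pediatric = <20) on the chosen basis
   (prevalence or incidence). Hospitalizations split the 1,209 national
   discharges by the segment's epidemiological share, then by severity,
   keeping unrounded intermediates; round-half-up is applied once, at
   reporting.
2. **Four costing scenarios** per segment:
   {prevalence, incidence} × {survey-reported treatment cost, national
   average prescription cost}. Components:
   - direct medical: treatment `m_s·N_s`, medical services (adults only),
     inpatient care `h_s · ALOS · c_day / fx`;
   - direct non-medical: associated (transport/accommodation) `a_s·N_s`;
   - indirect: absenteeism by the human-capital approach,
     `W_s · d_s · w·12/(251·fx)` for full-time workers (part-time at half
     the gross wage), for patients (adults) or caregivers (pediatric).
3. **EQ-5D-5L sub-analysis**: index utilities under a pluggable additive
   value set (`u = 1 − Σ decrements`), level-1 vs 2–5 dichotomization, and
   EQ-VAS summaries by age band.

The survey-processing stage diagnoses the missingness mechanism of adult
treatment costs (Little-type MCAR chi-square plus a logistic screen for
MAR) and completes the column by chained equations with predictive-mean
-matching draws before averaging. The seeded synthetic-survey module
generates cohorts with the study's structure (n=622 adults with severity
margin 141/368/113; n=57 caregivers with 22/21/14; exactly calibrated
per-severity cost means; value-dependent MNAR deletion), so the whole
pipeline is testable offline.

## Worked example

Cost the adult segment on the prevalence basis from the packaged Romanian
2022 inputs:

```bash
$ ad-coi cost --basis prevalence --segment adult --out cells.csv
grand total EUR 29,810,354.2; average/patient 564.6
```

The grand total is the 2022 national cost of AD for adults 20+ under the
prevalence-based, survey-treatment scenario: ~€29.81M, of which treatment
€7.86M, medical services €9.25M, hospitalization €0.72M, associated costs
€6.01M, and absenteeism €1.43M (full-time) + €4.54M (part-time). Dividing
by the 52,800 extrapolated prevalent cases gives €564.6 per patient-year.
`cells.csv` holds every component × severity cell in tidy form.

Run everything (synthetic cohorts → processing → extrapolation → all 8
scenario results → EQ-5D tables → manifest):

```bash
ad-coi run --out-dir out/ --seed 1
```

## Layout

| module | role |
|---|---|
| `adcoi.synth` | seeded synthetic survey cohorts, MNAR injector |
| `adcoi.processing` | missingness diagnosis, PMM imputation, input averages |
| `adcoi.extrapolate` | GBD-based severity stratification, discharge splitting, worker counts |
| `adcoi.costing` | unit costs, four-scenario engine |
| `adcoi.eq5d` | value-set scoring, dichotomization, EQ-VAS |
| `adcoi.pipeline` / `adcoi.cli` | orchestration, table rendering, `ad-coi` CLI |

Methodological details, parameter defaults and known limitations are in
`docs/methods.md`.
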