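# Methods

## Study design being implemented

The pipeline estimates the 2022 economic burden of atopic dermatitis (AD)
in Romania from a broad perspective: direct medical costs (treatment,
medical services, inpatient hospitalization), direct non-medical costs
(transport, accommodation and similar "associated" out-of-pocket
spending), and indirect costs (productivity losses from absenteeism,
valued by the human-capital approach). Costing is mixed by data
availability: bottom-up (per-patient survey averages × national case
counts) for treatment, medical services and associated costs; top-down
(apportioned national hospital discharges) for inpatient care; hybrid for
productivity. Results are produced for two epidemiological bases —
prevalence (all existing cases) and incidence (new cases in the year) —
and, within each, for two treatment-cost sources: the survey-reported
annual cost and the national average prescription value. That yields four
scenarios per population segment (adults 20+ years; pediatric <20 years,
whose survey data are caregiver-reported and lack the medical-services
category).

## Extrapolation and rounding

Severity shares enter as the integer survey counts (141/368/113 of 622
adults; 22/21/14 of 57 caregivers), never as rounded percentages: this is
what makes the national stratifications reproducible to the unit. All
chained computations use unrounded intermediates (e.g. the pediatric
discharge share 798.70 of 1,209 is split by severity before any rounding);
round-half-up is applied once, when a count is reported. Independent
per-stratum rounding means a segment's strata may miss the segment total
by up to n_strata/2.

One reference count is not reachable under this convention: the adult
prevalent severe stratum is 52,801 × 113/622 = 9,592.46, which rounds to
9,592, while the published figure is 9,593 (the published prevalence
strata were evidently forced to sum to the segment totals, while the
published incidence strata are independently rounded and sum to 8,515 and
13,126 — no single convention reproduces both; the underlying GBD crude
counts are themselves non-integer). `reproduce()` reports this cell
honestly as a mismatch; every monetary quantity downstream is insensitive
to it (<0.02%).

Worker counts per stratum are `round_half_up(cases × share)` with
employment shares taken from the survey. The packaged reproduction shares
were back-solved from the published national worker counts, because the
survey-internal employment margins were never published; notably the
moderate-severity full-time + part-time shares exceed 1 (17,125 + 21,477
workers against 31,239 cases), so the share-sum precondition is enforced
as a warning rather than an error. Likewise, caregiver mean absence days
are carried per basis in the fixtures: the published caregiver
productivity totals are not jointly consistent with a single per-worker
mean across prevalence and incidence (e.g. moderate part-time back-solves
to 66.97 days under prevalence but 267.84 under incidence). The pipeline
reproduces, and does not rationalize, these properties of the reference
results. Adult mean days are consistent across bases.

## Unit costs and currency

All survey costs are EUR/year; national unit costs are RON with a single
conversion rate `fx` (default 4.9315 RON/EUR, the 2022 annual average;
uniquely consistent with the published pairs 6,126 RON → €1,242.27 and
40.4 RON → €8.19). The reference material elsewhere implies ≈4.976
(1,094 RON → €219.85); `fx` is one config scalar and the discrepancy is
documented here rather than averaged away. The hospital tariffs 1,094/1,012
RON are treated as per-day costs — only `n × ALOS × tariff / fx` reproduces
the published hospitalization cells; the literal per-stay reading
(~8× smaller) remains available via `hospital_cost_basis: per_stay`.
Gross daily wage is `monthly × 12 / 251 / fx`; part-time is monetized at
exactly half the gross monthly wage, with no further FTE adjustment.
Per-patient averages divide by all cases in the stratum, not only
cost-incurring ones. Pediatric caregiver absence is monetized at the
caregiver's wage class regardless of whether the child missed school.

## Missing data

Adult treatment cost arrives with missing entries. The mechanism is
diagnosed with (i) a Little-type chi-square over missingness patterns,
`d² = Σ_j m_j (ȳ_j − μ̂_{o_j})' Σ̂_{o_j}⁻¹ (ȳ_j − μ̂_{o_j})` with
EM-estimated MVN mean/covariance and `df = Σ_j p_j − p` (columns are
z-scored first, making the statistic's affine invariance hold to machine
precision), and (ii) a logistic regression of the missingness indicator on
observed covariates. Conclusion rule (α = 0.05): MCAR if both screens are
silent; MAR if a covariate predicts missingness; otherwise MNAR is assumed
— it cannot be confirmed from observed data.

Imputation is multiple imputation by chained equations with
predictive-mean-matching draws (statsmodels `MICEData`; donor pool k=5,
m=5 completed datasets, 10 sweeps between draws — conventional defaults,
all configurable). The released point value per missing cell is the mean
across imputations, because downstream costing consumes one completed
table. Observed cells are never altered; zero-variance predictors are
dropped with a warning. PMM assumes MAR: under genuinely value-dependent
deletion the completed mean stays biased toward the observed values, which
the tests demonstrate rather than hide. Rubin's-rules variance pooling and
delta-adjusted MNAR sensitivity analysis are out of scope.

## Synthetic cohorts

The generator's defaults are the study conditions: 622 adults with
severity margin (141, 368, 113) and 57 caregivers with (22, 21, 14)
(stratified generation — margins are exact, never sampled); per-severity
cost means equal to the published input averages (adults: treatment
116.4/125.3/266.5, medical services 61.2/158.3/371.9, associated
71.3/97.7/219.2 EUR; pediatric: treatment 89/131/206.4, associated
109/177/427.3). Costs are log-normal (nonnegative, right-skewed — the
standard shape for expenditure data) with coefficient of variation 0.8
(not stated in the source; chosen once as typical for out-of-pocket
spending) and are calibrated to the exact target mean by multiplicative
rescaling after the draw. Missed days are Poisson per severity ×
employment class with means consistent with the packaged productivity
fixtures; EQ-VAS is normal per age band (published band moments), rounded
and clipped to 0–100; EQ-5D levels are drawn per dimension from simplexes
chosen to match the published problem frequencies. MNAR deletion removes
treatment costs with probability `logistic(a + strength·z)` of the
record's own standardized value, with the intercept solved so the expected
missing fraction equals the target rate (defaults: rate 0.15, strength 1.0
— the source reports MNAR but neither rate nor strength; strength 0
reduces to MCAR). Pre-deletion values are kept in a shadow column for
recovery scoring.

What the generator does **not** emulate: correlations between cost
categories within a record, longitudinal structure, clinician-assessed
severity, non-AD controls, or real employment–severity dependence beyond
the configured simplexes (part-time caregiving is generated only in the
moderate stratum by default, mirroring the zero cells in the published
productivity table). Passing tests therefore show the pipeline's
arithmetic and statistical machinery is correct under the assumed
structure, not that the survey's real joint distribution is captured.

## EQ-5D-5L

The index is additive: `u(state) = 1 − Σ_d decrement(d, level_d)`,
anchored at 1 for 11111; decrements are a data file (CSV: dimension,
level, decrement), not code. Romania has no national 5L tariff and the
reference analysis does not name the set it used, so the package ships a
synthetic illustrative tariff (`valueset_synthetic.csv`, floor −0.025)
and any tariff in the same dialect plugs in; published utility ranges are
treated as fixtures for the packaged set, not reproduction targets.
Dichotomization maps level 1 → "no problems", 2–5 → "problems". EQ-VAS
summaries use the sample SD (n−1) and linear-interpolation percentiles;
a group of one reports SD as NaN.

## Numerical and design choices

- Round-half-up (`floor(x+0.5)`) for all reported counts; banker's
  rounding is never used.
- Scenario results are additive by construction; the test suite asserts
  grand total = Σ components to €0.01, degree-1 homogeneity in counts, and
  that survey/prescription scenarios differ only in the treatment cell.
- Empty severity strata yield zero means with a flag and a warning rather
  than an abort.
- EM for the MCAR test: ridge 1e-10, tolerance 1e-6, ≤100 iterations;
  patterns are grouped so the common one-missing-column case costs two
  linear solves per sweep.
- Reported problem sizes: the calibration simulation for the MCAR test
  uses 1,000 replicates of n=150; imputation recovery uses n=2,488 (4×
  the adult cohort) with 20% MCAR deletion — desk-scale sizes chosen so
  the whole suite runs in seconds while keeping Monte-Carlo error well
  inside the asserted bands.
- Plotting is deliberately omitted; outputs are tidy CSVs and rendered
  tables, which is what the downstream comparisons consume.

## Known limitations

Presenteeism, friction costing, discounting, DALYs, uncertainty intervals
on the GBD inputs and controlled/uncontrolled AD distinctions are out of
scope. The reproduction fixtures (worker shares, mean absence days)
are calibrated artifacts, not survey facts. PMM imputation under the
generator's MNAR mechanism is knowingly biased; the pipeline reports the
diagnosis and the bias instead of claiming recovery.
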