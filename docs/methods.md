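# Methods

## Scope and data model

The package operates on a three-way linkage: a cancer registry (one row
per patient: sex, birth date, site, diagnosis date, SEER summary stage,
histology), a claims table (one row per dated diagnosis code, with
inpatient/outpatient setting), a death table (one underlying-cause code
per decedent), and an enrollment table (last date of insurance coverage).
Real linkages of this kind live in restricted enclaves, so the package
pairs the analysis pipeline with a generator of statistically analogous
synthetic linkages whose ground truth is known.

## Comorbidity ascertainment

A condition is present when, inside the qualifying window
`[diagnosis − W months, diagnosis − 6 months)` (half-open, calendar-month
arithmetic), the patient has ≥ 1 inpatient claim with a matching code, or
≥ 2 outpatient claims whose extreme service dates are **strictly more
than 30 days** apart. Supported windows are W ∈ {30, 54, 78} months,
default 30 (the choice made for the elderly cohorts the index targets);
the washout is fixed at 6 months to exclude diagnoses provoked by the
not-yet-registered cancer. Interpretation choices:

* "gap > 1 month" is implemented as > 30 days between outpatient service
  dates — unambiguous at day resolution and conservative;
* month offsets clamp the day-of-month (May 31 − 6 months → Nov 30), so
  windows are well defined for every calendar date;
* claims on or after the diagnosis date are excluded with a logged
  warning rather than an error, because registries and claims can share
  a date legitimately.

Codes are matched by prefix against a configurable catalog
(YAML-serialisable). The default carries Deyo-style ICD-9 prefixes for
the 16 Charlson-derived conditions, mild liver disease extended with
viral hepatitis B/C prefixes, and hypertension split into uncomplicated
(401) vs complicated (402–405). Exact national code lists vary by
protocol; the catalog is data, not code, precisely so users can swap in
their own.

## Endpoints

Deaths are classified by matching the underlying-cause code against the
index site's own code family plus a small shared set of ill-defined codes
attributable to any index cancer (a simplified, configurable version of
SEER-style cause-specific death classification; multi-primary logic is out
of scope because the registry model keeps first primaries only). Patients
without a death record by the death-data horizon are considered alive and
censored at `min(last enrollment date, death horizon)`. Index training
uses cause-specific survival data (noncancer death = event); prognosis
uses both causes as competing events. Patients missing from both death
and enrollment data are censored at 0 days and logged loudly — they
indicate a linkage failure.

## Survival engines

* **Cox regression**: Newton maximisation of the Efron partial likelihood
  (Breslow by flag), with step-halving, convergence at max |gradient|
  < 1e-8 or relative log-likelihood change < 1e-10, and covariance from
  the inverse observed information. Constant or duplicate design columns
  are rejected; monotone likelihoods (separation) are flagged by a
  RuntimeWarning when |coef| exceeds 10 and capped at 25. The
  implementation is cross-checked in the test suite against a brute-force
  likelihood scan on toy data and against lifelines to 1e-4 on random
  problems.
* **Kaplan–Meier / Aalen–Johansen**: the CIF increments are
  `Ŝ(t−)·d_k/n`, with `Ŝ` the all-cause product-limit estimator, so
  `CIF_cancer + CIF_other + S = 1` holds exactly at every time point.
* **Time-dependent AUC**: incident/dynamic definition — at each event
  time the cases are the subjects failing then and the controls those
  still at risk strictly later; tied markers count ½. The summary over a
  horizon is the Heagerty–Zheng concordance-weighted average with weights
  `2·f̂(t)·Ŝ(t)`. Because published "t-year AUC" phrasing is ambiguous
  between the value at t and the integral up to t, both modes are
  exposed (`integrated_to`, the default and the summary a practitioner's
  riskset-ROC software reports, and `at_time`, the incident AUC at the
  event time nearest the horizon).

## Index construction

The pre-deletion model ("Main18&11") contains age (years at diagnosis),
a male indicator, 18 condition indicators, and the 55 pairwise products
among the 11 most common conditions, where "most common" means largest
pooled ascertained counts, ties broken alphabetically (logged). The
negative-deletion loop deletes, per iteration, **every** condition whose
main-effect coefficient is strictly negative (exact zeros survive),
together with all interactions touching it, then refits; age, sex, and
interaction terms are never deletion triggers (interactions may stay
negative). The deleted set grows strictly, so the loop terminates in at
most 18 iterations; deleting all conditions raises a "model degenerate"
error. Rationale for batch (not one-at-a-time) deletion: the procedure's
published description removes the negative conditions "altogether" per
round and iterates until all main effects are positive.

Scoring sums the retained coefficients over a patient's present
conditions and present pairs. Deleted conditions contribute zero — so a
patient whose only conditions were deleted has TCCI 0 but level 1, not
level 0, because level 0 is reserved for patients with *none* of the 18
conditions. The level-2 rule applies the 0.66 cutoff to the full TCCI
including any negative interaction contributions, per the index
definition. The severe-illness override (CHF, COPD, dementia, CRF,
moderate/severe liver disease) codes level 2 regardless of score; with
the published weights this changes the single-condition classification
only for COPD (weight 0.26).

Folds are a pure function of patient id and seed (blake2b hash mapped to
[0,1); train < 0.5 ≤ validation < 0.75 ≤ test). This construction makes
the train/validation/test division of *any* subset of patients the
restriction of the global division — the compatibility property the
nested cohort-subset validation design requires — without enumerating the
subsets.

## Prognosis tables

Cumulative incidences are evaluated on a fixed integer day grid
(1 y = 365 d, 2 y = 730 d, 5 y = 1826 d) per stratum of site × sex ×
age band × stage × level (bands 65–74/75–84/85–94 by default; a 30–94
mode supports histology-specific analyses of distant-stage disease; the
"others" no-stage-information category is kept as its own stratum).
Small-stratum handling mirrors registry disclosure practice: flags at
n < 100 and n < 50, suppression below 5. A diagnosis-period stratifier is
generic (any year split); no therapy-specific logic is included.
Survivor prevalence counts, at each year end, patients diagnosed by then,
not known dead, and still enrolled, banded by whole-year survival time
(0–5, 6–10, 11–15, >15).

## Synthetic data

What the generator emulates:

* **Linkage structure** — ids present in claims/deaths/enrollment always
  resolve in the registry; at most one death per patient; deaths never
  precede diagnosis.
* **Comorbidity co-occurrence** — a latent-threshold (Gaussian copula)
  draw with one exchangeable correlation knob (default 0.2). Marginal
  prevalences are exact by construction; defaults are the published
  pooled prevalences for the five cancer cohorts aged 65–94.
* **Claims behaviour** — per present condition, homogeneous Poisson
  streams of inpatient (0.3/year) and outpatient (4/year) claims over an
  84-month pre-diagnosis horizon ending at the washout; with probability
  `washout_leak_rate` (default 0.05) a condition instead emits claims
  only inside the washout, modelling recent-onset disease invisible to a
  compliant ascertainment rule. Unmapped background claims (0.5/year)
  add noise that exercises code matching. The claims intensities have no
  published values; they were fixed once at magnitudes typical of
  chronic-disease management under universal single-payer insurance
  (frequent outpatient contact, occasional admissions) and give
  ascertainment sensitivity ≈ 0.95 at the default window.
* **Mortality** — competing exponential hazards: noncancer
  `h = baseline · exp(0.06·(age−65) + 0.49·male + Σ true weights)` with
  the published index coefficients as default truth, cancer hazard by
  site × stage tuned so long-run cause-of-death fractions resemble the
  published cohorts (liver/lung dominated by cancer death, breast mostly
  surviving). Death-cause codes use each site's own ICD-9 family and a
  rotating set of common noncancer causes; a sentinel prefix ("ZC") is
  attributable to every site so tests can exercise the classifier
  directly. Diagnoses are uniform over 2004–2014, enrollment runs
  through 2015, death data through 2016.
* **Noncancer arm** — same claims machinery with zero cancer hazard and
  an index date sampled uniformly over the study window (the population
  sampling rule of the original noncancer cohort is not public; this is
  a stand-in that keeps ascertainment windows well defined).

What it does **not** emulate: realistic ICD-9 co-occurrence beyond the
configured map, hospital-level clustering, treatment claims, seasonal or
secular claim trends, non-proportional hazards, or dependence between
comorbidity and stage at diagnosis. Passing tests therefore demonstrate
correctness of the *pipeline* under a known generative model, not the
epidemiology of any real population.

## Study scales and scenario choices

The parameter-recovery scenario (`recovery_scenario`) places nonzero true
weights on eight conditions held at prevalence ≥ 0.12 — seven positive
(at their published values) and one protective (Ulcer, −0.30) that the
deletion loop must remove — with an elevated noncancer baseline
(0.04/year) and halved cancer hazards. The design was powered a priori:
with ≈ 7,000 training-fold noncancer deaths at n = 50,000, each
main-effect standard error is ≈ 0.05–0.06, so the ±0.15 recovery band is
≈ 3 standard errors. Weights on conditions at their natural sub-1%
prevalence are kept at zero because no estimator can localise a
coefficient supported by a handful of subjects. The test suite runs the
same scenario at n = 20,000; the acceptance script at n = 50,000.
Fixture cohorts for unit tests use n ≈ 4,000, enough for the qualitative
properties they assert.

## Numerical conventions

* Dates are ISO strings in files, datetime64 in memory; all month
  arithmetic is calendar-month offset with day clamping.
* Step functions (KM, CIF) evaluate right-continuously; "probability at
  5 years" means the value at day 1826.
* Index weights round-trip through their plain-text file bit-exactly
  (`repr` of the float).
* Percentages in prevalence tables are rounded to one decimal; cells
  with 0 < count < 5 are masked.
* All randomness flows from explicit integer seeds; identical
  configuration and seed reproduce every output file byte-for-byte.

## Known limitations

Ascertainment reflects claims presence, not clinical severity. The
negative-deletion procedure trades a possibly better-calibrated model for
interpretability; retaining only nonnegative main effects can bias
scores for patients whose deleted conditions were genuinely protective or
confounded. The simplified cause-of-death map cannot reproduce the full
SEER attribution logic for multiple primaries. The hash-based folds
guarantee subset compatibility but not exact fold sizes (binomial
fluctuation around 1/2, 1/4, 1/4).
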