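# comorbindex

Claims-based construction of a cancer comorbidity index and
competing-risks "actual prognosis" tables, for epidemiologists and
biostatisticians working with linked cancer-registry / insurance-claims /
cause-of-death data.

Older cancer patients often die *with* their cancer rather than *of* it.
Treatment decisions therefore need the absolute probabilities of three
outcomes — dying of the cancer, dying of other causes, surviving — not
just net cancer survival. This package implements the full pipeline used
to produce such estimates for Taiwan's five most common cancers (breast,
colorectal, liver, lung, oral), including the Taiwan Cancer Comorbidity
Index (TCCI), and a synthetic-data generator that makes every stage
testable without access to the restricted national databases.

## The model

1. **Ascertainment.** Each of 18 comorbid conditions (a Charlson/NCI-style
   list with viral hepatitis folded into mild liver disease and
   hypertension split into uncomplicated/complicated) is detected from
   pre-diagnosis claims: one inpatient diagnosis, or two outpatient
   diagnoses more than 30 days apart, inside the window
   `[diagnosis − 30 months, diagnosis − 6 months)`. The final 6 months are
   a washout that removes diagnoses triggered by the cancer itself.
   54- and 78-month windows are available.

2. **Index fitting.** A Cox proportional-hazards model (Efron ties) for
   time from diagnosis to *noncancer* death — cancer deaths and loss to
   follow-up are censored — with covariates age, sex, all 18 conditions,
   and all 55 pairwise interactions among the 11 most common conditions
   ("Main18&11"). Conditions with negative fitted main effects are
   deleted outright (with their interactions) and the model refitted
   until every retained main effect is nonnegative. A patient's TCCI is

   `TCCI = Σ β̂_condition · x_condition + Σ β̂_pair · x_a x_b`

   over the retained terms; age and sex are reported but not scored.

3. **Comorbidity levels.** 0 = none of the 18 conditions;
   2 = TCCI > 0.66 or a severe illness present (CHF, COPD, dementia,
   chronic renal failure, moderate/severe liver disease); 1 = otherwise.

4. **Validation.** Deterministic hash-based train/validation/test folds
   (1/2, 1/4, 1/4) that restrict consistently to any cohort subset;
   discrimination measured by the incident/dynamic time-dependent AUC
   (Heagerty–Zheng) of the model's linear predictor at 1, 2, and 5 years.

5. **Actual prognosis.** Aalen–Johansen cumulative incidence of cancer
   death and other-cause death by site, sex, age band, stage, and
   comorbidity level, with small-stratum flags (n < 100, n < 50) and
   suppression of cells under 5.

The package ships the published TCCI weights
(`comorbindex.published_model()`), a configurable ICD-9 code map, and a
synthetic linked-data generator with known comorbidity prevalence and
cause-specific hazards for end-to-end parameter-recovery testing.

## Worked example

```python
from comorbindex import published_model, tcci_score, assign_level

model = published_model()
for present in [set(), {"CRF"}, {"COPD"}, {"AMI"}, {"CHF", "CVD"}]:
    score = tcci_score(present, model)
    level = assign_level(present, score)
    print(f"{sorted(present) or ['none']}: TCCI={score:.2f}, level={level}")
```

prints

```
['none']: TCCI=0.00, level=0
['CRF']: TCCI=0.80, level=2
['COPD']: TCCI=0.26, level=2
['AMI']: TCCI=0.27, level=1
['CHF', 'CVD']: TCCI=1.00, level=2
```

CRF alone exceeds the 0.66 cutoff; COPD alone does not but is coded 2 by
the severe-illness override; AMI alone stays at level 1. CHF + CVD sums
the two main effects (0.75 + 0.37) plus their interaction (−0.12).

End-to-end on synthetic data, from the shell:

```bash
comorbindex run --out run1            # simulate → ascertain → … → prognosis
comorbindex simulate --seed 7 --out data/
comorbindex ascertain --data data/ --window 30 --out asc/
```

`run` writes profiles, outcomes, fold assignments, fitted index weights,
validation AUCs, prognosis cells, and a `manifest.json` with content
hashes; reruns with the same seed reproduce the hashes exactly.

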