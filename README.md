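# emexposure

Maximum-likelihood estimation of the association between a rare binary
outcome and a binary exposure that is **missing for a large fraction of
subjects**, with a built-in sensitivity analysis for informative
missingness. The motivating setting is perinatal epidemiology: fetal
hypoxia at birth (ascertained from fetal scalp, umbilical arterial and
venous blood pH) as a risk factor for autism spectrum disorder in a
population birth cohort, where roughly half the children were never tested
for hypoxia.

## The model

For child *i* with outcome *Y*, exposure *X*, confounders *W* (birth
cohort, socio-economic class, gender) and maternal/obstetric covariates
*Z*:

```
outcome model    P(Y=1 | X, W) = logistic(β₀ + βₓ X + β'W)
exposure model   P(X=1 | Z)    = logistic(γ'Z) = π(Z)
```

When *X* is unobserved, its prior probability is tilted by a
**sensitivity ratio** r ∈ [0, 1]:

```
P(X=1 | Z, X missing) = r · π(Z)
```

r = 1 is the missing-at-random (MAR) assumption given (Z, Y); r < 1 says
untested children are systematically *less* likely to be exposed than
tested children with the same covariates — plausible when clinicians
order the test on suspicion. r cannot be estimated from the data; it is
fixed by the analyst and varied over a grid in sensitivity analyses.

Both models are fitted jointly by an EM algorithm:

* **E step** — each missing-exposure child gets the posterior weight
  w = r·π·f₁ / (r·π·f₁ + (1 − r·π)·f₀), where f₁, f₀ are the outcome
  likelihoods under X = 1 and X = 0;
* **M step** — the outcome model is refitted by weighted logistic
  regression on a pseudo-record expansion (each missing child appears as
  X = 1 with weight w and X = 0 with weight 1 − w), and the exposure
  model by a Newton maximization of the tilted objective (which at r = 1
  reduces exactly to a weighted logistic fit).

The observed-data log-likelihood increases every iteration; standard
errors come from the central-difference Hessian of that likelihood at the
optimum (a bootstrap is available as a cross-check), and effects are
reported as odds ratios with 95% Wald intervals.

The package also ships the pH-based exposure classifier (scalp pH < 7.25,
arterial pH < 7.20, venous pH < 7.28, strict inequalities; positive on at
least one performed test by default), descriptive tables
(test-combination ascertainment and outcome × exposure × gender rates
with binomial SEs), and a synthetic cohort generator with MCAR/MAR/NMAR
missingness whose NMAR ratio r is solved exactly per subject — so every
stage is testable without access to restricted registry data.

## Worked example

Simulate a cohort of 20,000 children (14% exposure prevalence among ~48%
tested, 0.5% outcome with a fivefold male excess, 52% of exposures
missing), then fit at r = 1 and sweep r:

```bash
emexposure simulate --out cohort.csv --seed 7 --n 20000
emexposure fit --input cohort.csv --schema cohort.csv.schema.yaml \
    --outcome-terms hypoxia,gender \
    --exposure-terms maternal_age,parity,smoking,preeclampsia,presentation,labor_type,apgar_low,birth_weight \
    --r 1.0 --out fit.json
```

`fit.json` reports (this exact run): converged in 13 iterations with
10,319 missing-exposure children handled; hypoxia OR **1.825**
(95% CI 0.990–3.366, p = 0.054) and male OR 3.430. The wide interval is
what a 0.5%-rare outcome at n = 20,000 buys.

```bash
emexposure sweep --input cohort.csv --schema cohort.csv.schema.yaml \
    --outcome-terms hypoxia,gender \
    --exposure-terms maternal_age,parity,smoking,preeclampsia,presentation,labor_type,apgar_low,birth_weight \
    --r-grid 0.1,0.2,0.5,0.7,1.0
```

```
                                r=0.1         r=0.2         r=0.5         r=0.7           r=1
deviation from MAR             strong        strong      moderate          weak    none (MAR)
odds ratio estimate             2.041         2.027         1.967         1.914         1.825
95% confidence interval  1.128, 3.693  1.114, 3.689  1.069, 3.617  1.038, 3.530  0.990, 3.366
p-value                         0.018         0.021         0.030         0.038         0.054
```

Reading the sweep: if untested children were only 10% as likely to be
hypoxic as tested children with the same covariates (r = 0.1), the
estimated odds ratio rises from 1.83 to 2.04 and the interval excludes 1 —
the inference is sensitive to the missingness assumption, which is the
point of the exercise.

The same machinery is available as a scikit-learn-style estimator:

```python
from emexposure import EMExposureLogit, read_cohort, CohortSchema

table = read_cohort("cohort.csv", CohortSchema.from_yaml("cohort.csv.schema.yaml"))
est = EMExposureLogit(
    outcome_terms=("hypoxia", "gender"),
    exposure_terms=("maternal_age", "parity", "smoking", "preeclampsia",
                    "presentation", "labor_type", "apgar_low", "birth_weight"),
    r=1.0,
).fit(table)
est.effect("hypoxia")   # EffectEstimate(odds_ratio=1.825, ci_low=0.990, ...)
```

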