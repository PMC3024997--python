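# Methods

## Problem and likelihood

We estimate the odds ratio between a binary outcome Y (a rare
neurodevelopmental diagnosis) and a binary exposure X (fetal hypoxia at
birth) when X is unobserved for roughly half the cohort. The joint model
factorizes as

    P(Y, X | Z, W) = P(Y | X, W; β) · P(X | Z; γ)

with both factors logistic: the outcome model in X, confounders W
(birth cohort, socio-economic class) and optionally gender and a
gender×X product term; the exposure model in categorical
maternal/obstetric covariates Z (reference-cell coding, first listed
category as reference). The structural assumption is that Z influences Y
only through X, so Z terms do not enter the outcome model.

For a child whose X is missing, the exposure prior is tilted by the
sensitivity ratio r ∈ [0, 1]:

    P(X = 1 | Z, missing) = r · π(Z),    π(Z) = logistic(γ'Z).

r is the ratio of exposure probabilities between untested and tested
children with the same covariates. r = 1 is missing-at-random given
(Z, Y); r < 1 encodes the clinical reality that testing is ordered on
suspicion. r is not estimable from the data (the likelihood is flat in r
once γ absorbs the level), so it is fixed by the analyst and varied over
the grid {0.1, 0.2, 0.5, 0.7, 1.0} in sensitivity sweeps, labelled
strong/strong/moderate/weak deviation from MAR.

The observed-data log-likelihood sums, over observed-exposure children,
log f(Y|X,W;β) + X log π + (1−X) log(1−π), and over missing-exposure
children the two-component mixture

    log[ f(Y|1,W;β)·rπ + f(Y|0,W;β)·(1−rπ) ].

## EM algorithm

* **E step.** Posterior exposure weight for each missing child:
  w = rπf₁ / (rπf₁ + (1−rπ)f₀) with f₁, f₀ the Bernoulli outcome
  likelihoods under X=1 and X=0. Weights are exact Bayes; the two
  pseudo-records of a child carry weights w and 1−w summing to one.
* **M step, β.** Weighted logistic fit on the pseudo-record expansion
  (observed rows at weight 1), by Newton with step-halving.
* **M step, γ.** Newton maximization of
  Q(γ) = Σ_obs [X log π + (1−X) log(1−π)] +
  Σ_miss [w log(rπ) + (1−w) log(1−rπ)], with an ascent-direction
  safeguard (for r < 1 the tilted term is not globally concave; in
  practice the safeguard never triggers on realistic data). At r = 1 the
  objective coincides with a weighted logistic log-likelihood on the same
  expansion, which is regression-tested.
* **Initialization.** Complete-case fits of both models on the
  observed-exposure records — cheap and consistent under MAR.
* **Convergence.** Parameter sup-norm change < 1e-6 (default), cap 500
  iterations; a fit that hits the cap is returned flagged
  `converged=False`. The observed-data log-likelihood is recorded every
  iteration and checked nondecreasing to 1e-8 relative tolerance; the EM
  fixed point is verified in tests against an independent BFGS
  maximization of the observed-data likelihood (agreement to 1e-4 on
  instances up to 500 records, at r = 0.1, 0.5 and 1).

## Inference

The default covariance is the inverse negated central-difference Hessian
of the observed-data log-likelihood at the optimum, joint over (β, γ),
with per-coordinate steps 1e-4·(1+|θ|). A nonparametric bootstrap
(resample children, refit, default 200 replicates, seeded) is available
as a cross-check; with no missing data the Hessian covariance matches
the standard logistic-regression covariance blockwise. Odds ratios are
exp(coef) with 95% Wald intervals (z = 1.959964) and two-sided p-values.
Gender-stratified analyses refit the exposure model within stratum; the
multiplicative gender×exposure interaction is tested by the Wald
statistic of the product coefficient, whose complete-data MLE on a
saturated 2×2×2 table equals the ratio of stratum odds ratios (tested).

## Numerical core

The weighted Bernoulli maximum-likelihood solver is Newton with
step-halving (up to 25 halvings), gradient sup-norm 1e-8 at exit,
probabilities clipped 1e-12 from the boundary so log-likelihoods stay
finite, rank-deficiency detection with the offending columns named, and
divergence past |coef| > 30 reported as separation. It must stay stable
under the tiny fractional weights a near-degenerate E step produces,
which is why step-halving Newton was chosen over plain IRLS.

## Synthetic cohorts

The generator emulates the structure of a provincial birth registry at a
scaled-down size (default n = 20,000): eight categorical covariates with
realistic prevalences drive a logistic exposure model calibrated to 14%
prevalence; the outcome is calibrated to 0.5% overall with a ~5:1
male:female ratio and a default true exposure OR of 1.5; gender is male
with probability 0.512. Model intercepts are solved once against a large
fixed calibration draw, so configured rates are targets in expectation.
A two-covariate variant with the same structure (`compact_config`) keeps
repeated-fit experiments cheap; recovery and coverage experiments use it
at n = 10,000–20,000 with 25–100 replicates, and sweep fixtures at
n = 50,000 — sizes chosen so a full verification run completes in a few
minutes on one core.

Missingness mechanisms:

* **mcar** — constant rate;
* **mar** — logistic in chosen Z/Y drivers, intercept solved on the
  realized cohort so the expected rate hits the target (default drivers:
  obstetric-intervention indicators, negative signs — complicated
  deliveries get tested);
* **nmar** — two independent triggers. The exposure trigger fires with
  probability a (X=1) or b (X=0), where a is solved per subject by
  bisection so that the probability ratio
  r = P(X=1|missing,Z) / P(X=1|observed,Z), marginally over the second
  trigger, equals the target exactly, and b is tuned for the overall
  rate. The outcome-linked trigger makes affected children less likely
  to go untested; its strength (log-odds −0.65, half the overall rate)
  was calibrated once so the simulated untested:tested outcome-rate
  ratio matches the ~0.72 observed in the motivating registry. This
  second channel is what gives the sensitivity sweep its characteristic
  monotone response: without it (set `outcome_miss_share=0` for the pure
  exposure-dependent mechanism), the fitted OR is almost flat in r and
  its direction of movement is sample-specific.

`empirical_r` validates generated cohorts: the crude ratio of true
exposure prevalences between missing and observed groups, or a
stratum-size-weighted version within Z cells (the construction is exact
per cell, so the stratified version is the matched validator; the crude
pooled ratio carries a small aggregation shift).

## What the simulations do and do not show

Recovery experiments demonstrate: consistency and ~95% Wald coverage of
the exposure log-OR under MAR; the published sensitivity pattern (OR
monotone nonincreasing in r, MAR estimate smallest) on cohorts with
informative missingness; and generator self-consistency. They also make
an honest negative point: when missingness depends on exposure (and
outcome) through channels that factorize, the MAR fit of the odds ratio
remains consistent, so refitting at the "true" r moves the point
estimate away from the truth rather than toward it. The r-sweep is
therefore a sensitivity analysis — *how would inference change if
untested children were less likely exposed* — not a bias correction, and
the package documents it as such.

Real registry data differ from the generator in ways the tests cannot
cover: misclassified exposures and outcomes, correlated covariates,
within-mother clustering, incomplete follow-up, and missingness driven by
unmeasured clinical judgment. Passing tests show the estimator does what
the model promises under the model's assumptions, not that those
assumptions hold in any particular registry.

## Degenerate inputs and edge policies

pH thresholds are strict; boundary values are negative; a fully absent
panel is "unknown". Children with absent covariates are excluded from
model fitting with a logged count; children with absent gestational age
are excluded only from full-term subsets. The exposure model requires
observed records at both exposure levels, else an identifiability error.
r = 0 zeroes every posterior weight; π → 0 makes a missing child's
likelihood contribution r-invariant. Zero-weight rows are dropped before
rank checks. The CSV missing token is the empty cell (configurable on
read). Sweep grids must be strictly increasing within [0, 1]; a
non-monotone OR profile on user data logs a warning (it usually means a
grid point did not converge) rather than raising.

## Known limitations

r is assumed constant across covariate patterns and is not estimable;
no Z-missingness model (complete-case in Z); no regularization, so
quasi-separated strata (tiny subgroups with zero cases) fail loudly
rather than shrink; the observed-Hessian covariance treats r as known,
understating uncertainty about the missingness mechanism itself —
precisely why results are reported across the whole r grid.
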