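# Methods

## Data-generating process

Each simulated subject carries three continuous confounders X₁–X₃ drawn
i.i.d. N(0, 1), three binary confounders X₄–X₆ with prevalences 0.1, 0.25
and 0.5, and a binary moderator M with prevalence 0.5 (or 0.1 in the
low-prevalence conditions). Treatment is assigned with probability

p = expit( α₀ + α_M·M + α_MX₁·M·X₁ + Σⱼ α_Xⱼ·Xⱼ + e₁ ),  e₁ ~ N(0, σ_e₁),

T ~ Bernoulli(p), and the outcome is

Y ~ N( β₀ + β_T·T + β_M·M + β_TM·T·M + β_MX₁·M·X₁ + Σⱼ β_Xⱼ·Xⱼ , σ_Y ).

Default coefficients (the base scenario): α₀ = 0.1, α_M = 0.3,
α_X = (0.3, 0.2, −0.1, 0.4, −0.2, 0.3); β₀ = 0.25, β_T = 1.5, β_M = 0.5,
β_X = (0.5, 0.5, −0.3, 1, 0.6, 1); cohort size n = 1000. The study grid
varies α_MX₁ ∈ {0, 0.1, 0.2}, β_MX₁ ∈ {0, 0.2, 0.4}, β_TM ∈ {0.3, 0.6} and
prev(M) ∈ {0.5, 0.1}: 36 scenarios, 500 replicates each by default. True
subgroup effects are β_{T|M=0} = β_T and β_{T|M=1} = β_T + β_TM.

**Noise-scale convention.** Both noise terms are specified by their
*standard deviation* (σ_e₁ = σ_Y = 0.2 by default), matching the
`rnormal(mean, sd)` convention of the Stata environment this class of study
is normally run in. Both scales are ordinary parameters of
`DGPCoefficients`, so the variance reading (σ = √0.2) can be simulated by
passing it explicitly; under the SD reading the Monte Carlo bias table
reproduces the reference pattern of results, which is why it is the
default.

**Latent treatment noise.** e₁ enters the *true* assignment probability but
is never visible to the estimators: every fitted propensity model omits it
by construction, exactly as unmeasured idiosyncratic assignment variation
would be omitted in practice. The carried `p` column exists only for
diagnostics.

## Estimators

For every cohort the estimand triple is (β̂_{T|M=1}, β̂_{T|M=0}, β̂_TM) with
β̂_TM ≡ β̂_{T|M=1} − β̂_{T|M=0} enforced by construction.

* **Regression adjustment** — OLS of Y on 1, T, M, T·M plus the adjustment
  model's confounder terms; for the stratified model (d), OLS of Y on 1, T,
  X₁…X₆ within each level of M. β̂_{T|M=0} is the T coefficient, β̂_TM the
  T·M coefficient; the SE of β̂_{T|M=1} uses the full coefficient
  covariance (var(T) + var(T·M) + 2 cov).
* **PS covariate adjustment** — the fitted PS enters the outcome model as a
  single linear term: Y ~ 1 + T + M + T·M + PS (per-stratum Y ~ 1 + T + PS
  for model d, with subgroup-specific PS).
* **IPTW** — weighted least squares of Y ~ 1 + T + M + T·M with
  unstabilised, untrimmed weights 1/PS (treated) and 1/(1−PS) (untreated)
  and HC1 sandwich standard errors.
* **PS matching** — each treated subject is matched to the control with the
  nearest PS, with replacement and no calliper; exact distance ties break
  to the lowest control row index (deterministic, order-independent). The
  matched-sample regression Y ~ 1 + T + M + T·M carries each treated
  subject with weight 1 and each control with its match frequency, with
  HC1 sandwich SEs on the weighted fit. In this convention weights enter
  the sandwich meat squared (the probability-weight convention); it is
  chosen deliberately because it displays the characteristic
  *overestimation* of the empirical SE that the matched/weighted methods
  are known for, whereas treating the frequencies as pure replications
  (row expansion) slightly underestimates it.

The outcome model of the PS-based methods deliberately contains no raw
confounders — the PS alone carries the adjustment. Adding them would make
the estimators doubly robust, a different class of method outside this
package's scope.

**Propensity models.** Maximum-likelihood logistic regression of T on the
adjustment model's terms: (a) 1 + M + X₁…X₆; (b) adds M·X₁; (c) adds all
M·Xⱼ; (d) two independent fits of 1 + X₁…X₆ within each level of M,
recombined into one score vector. Model (c) is a reparametrisation of (d)
(M main effect + all M·Xⱼ products ⇔ separate per-stratum coefficients),
so regression adjustment and IPTW give identical point estimates under (c)
and (d); this algebraic identity is used as a numerical oracle in the
tests (observed agreement ~1e−15).

**Matching estimand.** Controls are matched to treated subjects
(ATT-style selection). The direction is not critical at these treatment
prevalences (≈ 0.55 marginally), where ATT and ATE nearly coincide; it is
fixed rather than configurable to keep the 16-combination surface exact.

## Monte Carlo design

Replicate r of a scenario uses the seed stream
`SeedSequence([base_seed, 1000·α_MX₁, 1000·β_MX₁, 1000·β_TM, 1000·prev_M, r])`,
keyed on the scenario's parameters rather than its grid position. Any
subset of the grid therefore reproduces the corresponding draws of the full
grid bit-for-bit, and parallel execution (joblib, per-scenario tasks) is
identical to serial.

A replicate that cannot be estimated — a moderator stratum without both
treatment arms, or a non-converged/separated logistic fit — is recorded as
failed for the affected combinations and excluded from summaries, with
counts reported; there is no retry, which would bias the seed stream. At
the default conditions failures are essentially absent; they appear at
prev(M) = 0.1 with small n.

Per scenario and method × model combination the summaries report: mean
estimate; empirical SE (sample SD over completed replicates, n−1
denominator); average model SE computed as the root mean square of the
per-replicate model SEs; bias against the generating truth; normal-theory
95% intervals (mean ± 1.96 × empirical SE); and the Monte Carlo SE of the
mean (empirical SE/√reps), so every reported mean carries its own
uncertainty.

The **bias table** condenses one (β_TM, prev M) block into a 4 × 4 grid:
cell = (1/9) Σ over the block's nine (α_MX₁, β_MX₁) scenarios of
|mean(β̂_TM) − β_TM|. The absolute value is applied to the per-scenario
*mean* bias, not to per-replicate errors; the latter would be dominated by
Monte Carlo noise and could never approach the near-zero cells the
correctly specified methods produce. Note the statistic is a folded mean:
for a truly unbiased combination its expectation is ≈ 0.8 × the scenario
Monte Carlo SE rather than exactly zero, which sets the floor visible in
the near-zero cells (~0.001 at 500 replicates).

## What the generator does and does not emulate

The generator reproduces the structural features the study is about —
confounding on both scales, a moderator that modifies a confounder's effect
on either scale, realistic effect sizes and a moderately large cohort. It
does not emulate features of real observational data such as missingness,
measurement error, non-linear confounder effects, non-binary moderators,
treatment-induced confounding, or clustering/survey design. Passing tests
therefore demonstrate the estimators' behaviour under the stated model, not
robustness to those complications; the applied-analysis mode applies a
complete-case filter and otherwise assumes the user's columns already have
the required form.

## Numerical choices

* Logistic fits: `statsmodels.Logit`, Newton, maxiter 100; non-convergence,
  perfect separation or fitted probabilities at {0, 1} flag the replicate
  as failed rather than raising.
* Linear fits: `statsmodels` OLS/WLS; HC1 sandwich where robust SEs are
  specified (Stata's `, robust` analogue), conventional model-based SEs for
  regression and PS covariate adjustment.
* Stratified fits: se(β̂_TM) = √(se₁² + se₀²), exact under independence of
  the two stratum fits.
* Matching: scores sorted once (stable sort), nearest neighbour found by
  binary search; O(n log n), deterministic, with the lowest-row-index tie
  rule verified against a brute-force quadratic oracle in the tests.
* No PS truncation or weight trimming anywhere: the inverse-logit keeps
  fitted scores strictly inside (0, 1), and the study's estimators are
  deliberately the plain, untrimmed versions.
* CSV outputs use `%.17g` floats and re-reads use round-trip parsing, so
  `summarize` on written replicate files is bit-identical to the in-memory
  summaries.

## Problem sizes used in the tests and the acceptance script

The test suite runs one full (β_TM = 0.3, prev M = 0.5) block at the
study's native 500 replicates — the block used for the bias-table,
bias-pattern and SE-behaviour checks — plus a 200-replicate no-confounding
calibration run; both are exact study conditions, not scaled-down
surrogates. The acceptance script runs the complete 36-scenario grid at
500 replicates. Property and unit tests use closed-form cases, small
hand-built designs and large single cohorts (n up to 50 000 for parameter
recovery) as appropriate to each check.

## Known limitations

* Model standard errors ignore the estimation uncertainty of the PS itself
  (as do the plain robust SEs they model); this is part of the phenomenon
  under study, not a defect, but the SEs should not be reused as if
  efficient.
* The matching SE convention is one of several defensible sandwich
  variants; point estimates are unaffected by the choice.
* The applied-analysis mode estimates the same triple on user data but
  makes no claims about survey weights, missing-data mechanisms or
  moderator dichotomisation.
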