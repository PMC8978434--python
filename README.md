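# temsim

Monte Carlo simulation and estimation toolkit for **treatment-effect
modification (TEM) under moderator–confounder interactions**.

## The problem

In observational studies, researchers often ask whether a treatment effect
differs between subgroups defined by a binary *moderator* M (for example,
whether the effect of a health condition on well-being differs by sex or
smoking status). Confounding is routinely adjusted for with outcome
regression or propensity-score (PS) methods. A subtle failure mode arises
when the moderator also modifies the effect of a *confounder* — on treatment
receipt (a non-zero α_MX₁ coefficient in the treatment model) or on the
outcome (a non-zero β_MX₁ in the outcome model). Standard adjustment that
pools the confounder effect across subgroups then under-adjusts in one
subgroup and over-adjusts in the other, biasing the subgroup-specific
treatment effects β_{T|M=1}, β_{T|M=0} and the interaction estimate
β_TM = β_{T|M=1} − β_{T|M=0}, even though every confounder was "adjusted
for".

`temsim` generates cohorts from a fully specified data-generating process,

```
logit P(T=1) = α₀ + α_M·M + α_MX₁·M·X₁ + Σⱼ α_Xⱼ·Xⱼ + e₁,   e₁ ~ N(0, 0.2)
Y ~ N( β₀ + β_T·T + β_M·M + β_TM·T·M + β_MX₁·M·X₁ + Σⱼ β_Xⱼ·Xⱼ , 0.2 )
```

with three standard-normal confounders X₁–X₃ and three binary confounders
X₄–X₆ (prevalences 0.1, 0.25, 0.5), and measures the bias and precision of
β̂_TM under

* **four adjustment methods** — (1) regression adjustment, (2) PS covariate
  adjustment, (3) inverse-probability-of-treatment weighting (IPTW),
  (4) 1:1 nearest-neighbour PS matching with replacement; crossed with
* **four adjustment models** — (a) main effects of M and X₁…X₆ only,
  (b) plus the single M·X₁ product, (c) plus all six M·Xⱼ products,
  (d) fully stratified by M (subgroup-specific PS / outcome models).

The headline result the simulation reproduces: regression-based methods are
biased exactly when the interaction sits in the **outcome** model
(β_MX₁ > 0), the weighting/matching methods when it sits in the
**treatment** model (α_MX₁ > 0), and only subgroup-stratification (d)
rescues PS covariate adjustment.

## Worked example

Estimate subgroup effects on one simulated cohort with the largest
moderator–confounder interactions (α_MX₁ = 0.2, β_MX₁ = 0.4, true subgroup
effects 1.8 and 1.5, true TEM effect 0.3):

```python
from temsim import DGPCoefficients, generate_cohort, TEMEstimator

coeffs = DGPCoefficients(alpha_mx1=0.2, beta_mx1=0.4, beta_tm=0.3)
df = generate_cohort(coeffs, seed=42).to_frame()
X = df[["T", "M", "X1", "X2", "X3", "X4", "X5", "X6"]]

for model in ("a", "d"):
    est = TEMEstimator(method="iptw", adjustment_model=model).fit(X, df["Y"])
    print(f"model {model}: effect(M=1)={est.effect_m1_:.3f}  "
          f"effect(M=0)={est.effect_m0_:.3f}  "
          f"TEM={est.tem_:.3f} (SE {est.se_tem_:.3f})")
```

prints

```
model a: effect(M=1)=1.905  effect(M=0)=1.441  TEM=0.465 (SE 0.157)
model d: effect(M=1)=1.806  effect(M=0)=1.510  TEM=0.296 (SE 0.160)
```

Ignoring the interactions (model *a*) overstates the M=1 effect, understates
the M=0 effect and inflates the TEM estimate to 0.465; the stratified
adjustment (model *d*) recovers the generating values (1.8 / 1.5 / 0.3)
within sampling error on this single cohort of n = 1000.

`TEMEstimator` follows scikit-learn conventions (`fit`, `get_params`,
fitted attributes with trailing underscores) and accepts any number of
confounder columns, so the same estimator drives the applied-analysis mode
for user-supplied data.

## Command line

```bash
temsim make-config --out study.yaml          # default study conditions
temsim simulate --config study.yaml --out-dir out/ --jobs 4
temsim summarize --in-dir out/               # recompute summaries from files
temsim apply --data survey.csv --outcome wellbeing --treatment tinnitus \
             --moderator smoker --confounders age,bmi,sex \
             --method iptw --interactions all
```

`simulate` writes one per-replicate file per scenario, one summary file per
(β_TM, prevalence-M) block (means, empirical SEs, average model SEs, biases,
95% intervals, Monte Carlo SEs) and a combined average-absolute-bias table;
the exact configuration and seed are echoed to `config.yaml` for
provenance.

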