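# causalkit

Multi-step causal inference for high-dimensional observational cohorts.

Observational clinical registries — the motivating case is rehabilitation
outcomes after moderate-to-severe traumatic brain injury — assign treatments
by indication: sicker patients are more likely to receive surgery, to start
rehabilitation late, or to stay longer. Naive outcome comparisons are then
badly biased. `causalkit` implements a complete pipeline for estimating
average treatment effects (ATEs) from such data, exercised end to end on
synthetic cohorts with known ground truth:

1. **Synthetic cohorts** (`synthcohort`) — mixed binary/continuous
   covariates, a latent severity factor influencing treatment and outcome,
   logistic treatment assignment, linear-plus-noise outcomes with a known
   constant effect, an optional continuous exposure (days to rehabilitation)
   and registry-style placeholder missingness codes. Every draw is
   reproducible from `(config, seed)` and ships with a truth ledger.
2. **Cohort construction** (`cohort`) — placeholder recoding to NaN,
   composite variable-retention scoring (drop at >60% missing or >90%
   invalid), extreme-contrast binarization of a continuous exposure
   (e.g. ≤4.5 days vs ≥45 days, intermediate band excluded), and min-max
   outcome normalization with SD ≥ 0.15 / missingness ≤ 30% selection.
3. **Confounder selection** (`oal`, `cgnn`) — outcome-adaptive LASSO
   minimizing

   `L(β) = Σᵢ (yᵢ − xᵢβ)² + λ Σⱼ wⱼ|βⱼ|,  wⱼ = |β̂ⱼ|^(−γ)`, γ = 2,

   with the treatment never penalized and λ chosen on a 10⁻¹⁵…10⁰ grid by
   cross-validation; plus a DAG-constrained structure learner (acyclicity
   via `h(A) = tr(exp(A∘A)) − d = 0`, augmented Lagrangian) with bootstrap
   edge stability and a consensus top-k ranking across both methods.
4. **Effect estimation** (`estimation`) — propensity scores
   `eᵢ = P(Tᵢ=1|Xᵢ)`, inverse-probability weights `wᵢ = 1/eᵢ` (treated) or
   `1/(1−eᵢ)` (untreated), winsorized at the 1st/99th percentiles, Hájek
   ATE contrast; doubly robust AIPW; percentile bootstrap inference; and a
   causal-effect variational autoencoder (CEVAE) for latent confounding,
   trained on the ELBO with a β-weighted KL term (β = 0.5) and read out by
   Monte-Carlo sampling of `E[Y|T=1,z] − E[Y|T=0,z]`.
5. **Diagnostics** (`diagnostics`) — confounder-count sensitivity with the
   same-direction / |ΔATE| < 0.001 concordance rule, a five-family
   treatment-predictability suite (flagging confounding by indication when
   average held-out accuracy exceeds 0.9), and a six-method composite
   feature-importance table.

## Worked example

```python
import numpy as np
from causalkit import (SimulationConfig, generate_cohort, estimate_propensity,
                       ipw_weights, trim_weights, ipw_ate, aipw_ate, naive_ate)

cohort = generate_cohort(SimulationConfig(n_subjects=5000, true_ate=0.5,
                                          confounding_strength=1.0, seed=1))
y = cohort.outcomes["outcome_1"].to_numpy()
X = cohort.covariates[cohort.covariate_names("confounder")]

print("naive:", round(naive_ate(cohort), 4))
e = estimate_propensity(X, cohort.treatment).scores
w = trim_weights(ipw_weights(e, cohort.treatment))
print("ipw:  ", round(ipw_ate(y, cohort.treatment, w).ate, 4))
print("aipw: ", round(aipw_ate(y, cohort.treatment, X).ate, 4))
```

```
naive: 0.7536
ipw:   0.5124
aipw:  0.4918
```

The naive contrast overstates the true effect (0.5) by ~50% because
treatment assignment is driven by the same covariates as the outcome;
propensity weighting and the doubly robust estimator both recover it to
within a few hundredths.

A command-line interface mirrors the stages:

```bash
causalkit simulate --seed 1 --out sim/
causalkit preprocess --input sim/cohort.csv --codes 999,-1 --out clean/
causalkit select   --input sim/cohort.csv --outcomes outcome_1 --out sel.json
causalkit estimate --input sim/cohort.csv --outcomes outcome_1 \
                   --methods ipw,aipw --bootstrap 200 --out ate.csv
causalkit diagnose --input sim/cohort.csv --outcomes outcome_1 --out diag/
```

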