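# Methods

This note documents the models implemented in `causalkit`, the design of
the synthetic cohort generator, and the numerical choices that matter.

## Problem setting

The package targets effect estimation from observational cohorts in which a
binary treatment T is assigned by indication: baseline severity influences
both the treatment decision and the outcome Y, and part of that severity
may be unmeasured. The estimand throughout is the population average
treatment effect ATE = E[Y(1)] − E[Y(0)]. Because real registry data of
this kind is access-restricted, the pipeline is developed and validated
against a synthetic generator whose ground truth is fully recorded.

## Synthetic cohort generator

`generate_cohort` draws, for n subjects:

- **Covariates.** `n_confounders + n_instruments + n_noise` columns;
  within each role block columns alternate standard-normal and
  Bernoulli(0.5), mimicking a registry's mix of continuous scales and
  binary findings. When `latent_dim > 0`, continuous columns carry a fixed
  loading (0.8) on the first latent factor, making measured covariates
  noisy proxies of latent severity — exactly the X ~ p(X|z) structure the
  CEVAE posits, which is what makes latent recovery well-posed.
- **Treatment.** T ~ Bernoulli(expit(a₀ + Xᶜα + latent term)), with binary
  covariates centered in the score. The intercept a₀ is solved numerically
  so the mean propensity equals `treated_fraction` (default 0.4). The
  resulting per-subject probability is stored as the true propensity.
- **Outcomes.** Y = β₀ᵀXᶜ + latent term + `true_ate`·T + σε, ε ~ N(0,1).
- **Exposure days.** In `continuous-days` mode, a severity-driven
  lognormal, log days = 2.5 + 0.9·severity + 0.4·ζ (median ≈ 12 days),
  chosen so that both extreme-contrast tails (≤4.5 and ≥45 days) hold
  hundreds of subjects at n = 5000 and the cut induces genuine confounding
  by indication.
- **Coefficient scale.** Confounder and instrument coefficient blocks are
  drawn U(0.15, 0.35), all positive, and normalized by √(block size), so
  `confounding_strength` — not the covariate count — governs the total
  confounding signal. At strength 1 this produces a naive-estimator bias of
  roughly 0.3 outcome units with true propensities inside ≈ (0.01, 0.98):
  strong, clearly detectable confounding that still respects positivity.
  Positive coefficients make the naive bias monotone in the strength
  parameter, which is a tested invariant. Instruments share the
  treatment-model scale so that zero strength yields a treatment assignment
  independent of every covariate.
- **Missingness.** Placeholder injection is MCAR only: a fraction
  `missing_rate` of covariate cells is replaced by integer codes (default
  999, −1). MAR/MNAR mechanisms are out of scope.

What the generator does **not** emulate: time-varying confounding and
treatment-confounder feedback, informative (MAR/MNAR) missingness,
measurement error in outcomes, and the full width (hundreds of variables)
of a real registry. Passing tests therefore demonstrate correctness of the
estimators under the stated generating model, not performance guarantees on
real registry data.

## Cohort construction

Placeholder codes are recoded to NaN; each variable then receives
completeness (share non-missing) and quality (share valid, non-placeholder)
scores. The retention score is their unweighted mean — the combiner is a
package choice, with both raw components reported so alternative weightings
are auditable. Drop rules: missingness > 0.60, else invalid share > 0.90.
Clinical-relevance and redundancy exclusions are expert judgments and are
accepted only as an explicit user-supplied list.

Extreme-contrast binarization maps a continuous exposure to T = 1 / T = 0 /
excluded using inclusive cuts (value ≤ low or ≥ high); boundary values
belong to the extreme groups. Outcome normalization is min-max to [0, 1],
using theoretical scale bounds when supplied (e.g. a 1–7 ordinal scale) and
the empirical range otherwise; outcomes are excluded for missingness >
30%, a degenerate (constant) scale, or normalized SD < 0.15.

## Outcome-adaptive LASSO

The selection model is an outcome regression of Y on (T, X) with
per-coefficient penalties λ wⱼ|βⱼ|, wⱼ = |β̂ⱼ|^(−γ), γ = 2, where β̂ comes
from an initial joint least-squares fit (ridge-stabilized when requested;
the initial fit is joint rather than marginal — an assumption, recorded
here). Weights are capped at 10¹² for initial coefficients below 10⁻⁶ to
keep arithmetic finite. The treatment column is never penalized, so the
exposure cannot be dropped. Missing covariate cells are mean-imputed before
fitting and the imputed columns are reported.

The solver is cyclic coordinate descent with exact soft-threshold updates
and warm starts from the strongest penalty downward; convergence is on a
maximum coefficient move of 10⁻¹². Every returned path point is certified
against the subgradient (KKT) conditions of the weighted objective, with
violations required to stay below 10⁻⁶. λ is selected on the default grid
10⁻¹⁵…10⁰ (16 log-spaced points) by K-fold cross-validated prediction
error; fold-level refits reuse the full-data adaptive weights. A weighted
absolute-mean-difference (wAMD) criterion — the propensity-side rule used
in some formulations of outcome-adaptive selection — is exposed as a
clearly flagged alternative (`lambda_criterion="wamd"`).

## DAG-constrained structure learning

Nodes are the covariates, treatment and outcome (standardized). The learner
minimizes a self-reconstruction loss (1/2n)‖M − MA‖² plus an L1 sparsity
penalty, subject to the differentiable acyclicity characterization
h(A) = tr(exp(A∘A)) − d = 0 enforced by an augmented-Lagrangian schedule
(penalty weight ×10 per outer iteration, capped at 10¹⁶) until
h ≤ 10⁻⁸. The acyclicity penalty is the standard differentiable choice for
a DAG constraint. Because the loss depends on the data only through the
d×d Gram matrix, each inner step costs O(d²) regardless of n, which is what
makes 100+ bootstrap refits cheap. The L1 term is applied proximally
(soft-threshold after each Adam step), giving exact zeros; edges out of the
outcome node are masked to exact zero (the outcome causes neither
covariates nor treatment). Edges are "selected" at |A| > 0.1 on the
standardized scale — the raw weights are reported alongside so the
threshold's effect is checkable. A two-hidden-layer ReLU readout estimates
E[Y|T, X] and reports train/test R² on an 80/20 split.

Bootstrap stability refits on row-resamples with 1/5 the inner epochs and a
third of the outer iterations; stability is the per-edge selection
frequency. Consensus ranking averages the min-max-normalized
outcome-set selection frequency (adaptive LASSO) with the normalized edge
evidence toward treatment and outcome (stability when available, else |A|),
breaking ties lexicographically; the top-k (default 25) set feeds the
estimators. The combiner is a package choice: the requirement it implements
is "consistently identified across methods".

## Effect estimation

**IPW.** Propensity scores from an unpenalized logistic model (maximum
likelihood; scores clipped to [10⁻⁶, 1−10⁻⁶]; perfect separation degrades
to a warning with a ridge-regularized refit). Weights 1/e and 1/(1−e) are
winsorized at the 1st/99th percentiles — clamping rather than subject
exclusion, preserving sample size; an exclusion mode would be a trivial
variant but winsorization is the default reading of "handling extreme
scores". Winsorization recomputes interpolated percentiles from its input
and is therefore only approximately idempotent (the range contracts
monotonically; constant vectors are fixed points). The ATE uses the Hájek
(weight-normalized) contrast, which is invariant to weight rescaling and
bounded; Horvitz–Thompson behavior is recovered by skipping normalization.
The analytic CI uses a robust variance approximation for ratio-form
weighted means with weights treated as fixed; p-values come from a normal
reference. Both alternatives are behind flags: `normalize=False` gives the
Horvitz–Thompson form, `trim_weights(..., mode="exclude")` drops rather
than clamps the tail weights. A winsorized design necessarily trades a small bias for
variance: at the default generator's strength 1 the residual bias of
trimmed IPW is ≈ 0.03 outcome units at n = 5000.

**AIPW.** The influence-function estimator ψᵢ = m₁ − m₀ + T(Y−m₁)/e −
(1−T)(Y−m₀)/(1−e) with per-arm linear outcome models; consistent if either
nuisance model is correct (tested by deliberately breaking each in turn).
SE = sd(ψ)/√n.

**Bootstrap.** Percentile intervals over joint row-resamples with full
re-estimation per replicate; the two-sided p-value against zero is
2·min(frac ≤ 0, frac ≥ 0) floored at 1/(B+1). Replicates on which the
estimator fails are dropped and counted; more than 5% drops aborts.

**CEVAE.** Generative model z ~ N(0, I), T ~ Bern(σ(f_t(z))),
X ~ N(f_x(z), Σ), Y ~ N(f_y(T, z), σ²); Gaussian encoder q(z|X, T, Y).
Training maximizes the ELBO with a β-weighted KL term (β = 0.5). The
outcome decoder uses two potential-outcome heads (one per arm) rather than
a scalar treatment input: with a single head the treatment contrast is
systematically under-expressed, which development simulations showed as a
downward-biased ATE. Networks are compact numpy MLPs (hidden width 32, two
hidden encoder layers) with manual gradients and Adam (lr 5·10⁻³, batch
512, 60 epochs). Sixty epochs is deliberate: much longer training lets the
counterfactual heads drift in regions dominated by one arm (the classic
extrapolation failure), degrading ATE recovery. The ATE is the Monte-Carlo
average of f_y1(z) − f_y0(z) with z resampled from the posterior and
MC-dropout masks resampled per draw (identical masks serve both arms within
a draw, so tying the heads yields an exact zero). Inference conditions on
observed (X, T, Y) through the encoder, standard CEVAE practice. The
reported interval is the 2.5/97.5 percentile of the per-draw population
ATEs — a spread over model uncertainty, intentionally narrower than a
sampling-based CI.

## Diagnostics

**Confounder-count sensitivity** re-estimates each (method, outcome) effect
with nested top-k confounder sets (default k ∈ {20, 25, 30}) and scores
each k-pair concordant when effect directions match and |ΔATE| < 0.001.
The ±0.001 band is meaningful at registry scale: re-estimating with extra
covariates perturbs a weighted estimate by O(1/√n), ≈ 0.01 at n ≈ 3000, so
at desk-scale n the rule classifies almost all pairs discordant even when
directions agree perfectly. The acceptance script reports the honestly
computed concordance at n = 3000 together with the maximum |Δ|; direction
agreement is the informative part of the report at that scale.

**Treatment predictability** fits five classifier families — L2 logistic
(C grid 0.1/1/10), random forest (200 trees, depth 6/8/10), RBF SVM
(C 0.1/1/10), gradient-boosted trees (learning rate 0.05/0.1/0.2, depth
6), Gaussian naive Bayes — tuned by 5-fold grid search on a stratified 70%
split and scored on the held-out 30%. Average held-out accuracy above 0.9
raises an explicit confounding-by-indication warning: if baseline
covariates almost determine treatment, effect estimates rest heavily on
extrapolation. The flag logic is the testable unit; the clinical reading
belongs to the analyst.

**Composite importance** averages six min-max-normalized (0–100) scores per
covariate: ANOVA F, mutual information, random-forest impurity importance,
absolute standardized logistic coefficients, recursive feature elimination
(logistic base — the base estimator is a package choice), and absolute
point-biserial correlation (the "linear association" reading). Constant
covariates score 0. Exact duplicates tie on the four symmetric methods;
tree ensembles and RFE split credit between duplicates, which the report
surfaces as rounded-score ties.

## Problem sizes and determinism

All stochastic stages take explicit seeds; the CEVAE's default seed is the
constant 20250125. Test and script problem sizes are chosen for single-CPU
runs: recovery and coverage simulations use n = 5000 cohorts (100 and 100
seeds in the test suite; 20 and 50 in the acceptance script, with B = 200
bootstrap replicates), adaptive-LASSO selection uses n = 2000 over 25
seeds, structure stability uses n = 1000 chains with B = 100 bootstrap
refits, and the latent-confounding comparison uses n = 5000 over 25 (suite)
or 10 (script) seeds with 200 Monte-Carlo draws. Production-scale settings
(B = 1000, 1000 MC draws) are the library defaults.

## Known limitations

- Binary treatments only; continuous or multi-arm exposures must be
  binarized (the extreme-contrast design exists for exactly that purpose,
  at a known cost in generalizability).
- The structure learner's reconstruction is linear in the parents; the
  nonlinearity lives in the readout. No claim of full causal-discovery
  correctness is made — the graph is used for confounder ranking.
- CEVAE estimates depend on architecture and early stopping; they are
  exploratory alongside IPW/AIPW, mirroring how latent-confounder models
  should be used in practice.
- The ±0.001 concordance band (see above) is scale-dependent.
- MCAR missingness and mean imputation only; no imputation engine.
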