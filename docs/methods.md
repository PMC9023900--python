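# Methods

## The problem

A single loss-minimising prediction model is rarely the only defensible
one: many models fit almost as well, and they can rely on variables very
differently. Judging a variable's importance from the optimal model alone
can therefore overclaim (or underclaim) its relevance to the prediction
task. This package quantifies Shapley-based global variable importance
*across* the set of near-optimal logistic regressions — the Rashomon set —
and pools the per-model values into an overall importance with formal
uncertainty.

## Model reliance via Shapley values

Let `X_1 … X_d` be predictors, `Y` a binary outcome, and `f` a logistic
model with mean log-loss `L(f)`. For a coalition `S ⊆ {1..d}` the global
value function is

    v_f(S) = L(mean prediction) − L(f with only X_S known),

where variables outside `S` are integrated out against a background
("reference") sample of predictor rows — the marginal-distribution
approximation, which assumes some independence between in- and
out-of-coalition variables. The Shapley value

    φ_j(v_f) = (1/d) Σ_{S ⊆ D\{j}} C(d−1, |S|)^{-1} [v_f(S ∪ {j}) − v_f(S)]

attributes the total loss reduction `v_f(D)` additively among variables
(efficiency), and equals the average marginal contribution of `X_j` over
all `d!` orderings. The same formula with
`v_{f,x}(S) = E[f(X_D) | X_S = x_S]` gives the per-instance SHAP
attribution; the mean absolute SHAP value over instances is the
conventional single-model importance ranking that the ensemble-level
analysis is contrasted with.

### Estimation

`exact_shapley` evaluates the subset-weighted formula on an explicit
`2^d` coalition table (`d ≤ 12`) and is the oracle used in tests.
`sage_estimate` samples orderings: for each sampled permutation the
variables enter one at a time and each variable's contribution is the
drop in evaluation loss when it joins. Its standard error is the standard
deviation of a variable's contributions divided by `√n_permutations`.

The marginal expectation can be taken two ways:

* `marginal_batch=None` averages predictions over the entire reference
  sample at every step. This is the lowest-variance choice and the one
  that converges exactly to the enumerated coalition table; its standard
  errors reflect only the sampling of orderings, so contributions of
  variables a model barely uses can have standard errors orders of
  magnitude below the rest.
* `marginal_batch=q` (default 64) draws a fresh batch of `q` reference
  rows, with replacement, for every coalition evaluation. Successive
  evaluations then carry independent Monte-Carlo noise of similar size
  for every variable and model. This is how the canonical sampling-based
  implementation of the global Shapley value behaves, and it matters
  downstream: inverse-variance pooling is only well behaved when the
  within-model variances are commensurate (see below). The price is a
  small convexity bias — the loss of a batch-averaged prediction exceeds
  the loss of the fully averaged one by `O(var(p)/q)` — which is shared
  across models and negligible at the default batch size relative to
  between-model spread.

## Near-optimal models: the Rashomon sampler

The Rashomon set at tolerance `ε` contains every model of the class with
mean loss `≤ (1+ε) L*`, where `L*` is the optimal model's loss
(`ε = 0.05` by default). Because the loss is the *mean* log-loss, the
bound does not depend on the sample size. Proposals are drawn as

    k_i ~ Uniform(u1, u2),   β_i ~ N(β*, k_i Σ*),

with `Σ*` the inverse observed information of the fit, and rejected when
the training loss exceeds the bound; accepted proposals are thinned
uniformly to `final_size` (default 350) and the optimal model is always
included as row 0. All randomness comes from one seed.

Tuning matters: `Σ*` scales like `1/n`, so small multipliers produce
proposals far inside the Rashomon set and an ensemble that clusters
around the optimum, under-representing the loss range and — more
importantly — the flat coefficient directions (collinear variables) along
which near-optimal models genuinely differ. The defaults
`u1 = 20, u2 = 80, m0 = 1200` were chosen with `tuning_report`, which
bins the accepted losses over `[L*, (1+ε)L*]`: on the shipped default
scenario they give roughly uniform bin occupancy at ~30% acceptance and a
full 350-model ensemble. For other datasets, re-tune with
`tuning_report` until no bin is empty; acceptance near 100% signals
under-dispersion.

## VIF adjustment

Strong collinearity can push the marginal-approximation Shapley value of
an informative variable far negative. Following the model-reliance
definition used here, a variable whose variance inflation factor
(`VIF_j = 1/(1−R²_j)`, computed once from the training predictors)
strictly exceeds the threshold `v = 2` contributes through its absolute
value; unflagged variables keep their sign. Standard errors are not
changed by the adjustment.

## Pooling: DerSimonian–Laird random effects

Each of the `M` models is treated as a study reporting value `x_m` with
known variance `σ_m²`. With `w_m = 1/σ_m²`:

    Q  = Σ w_m (x_m − x̄_w)²,
    C  = Σ w_m − (Σ w_m²)/(Σ w_m),
    τ² = max(0, (Q − (M−1))/C),

then re-weighting by `w'_m = 1/(σ_m² + τ²)` gives the overall mean and
its variance `1/Σ w'_m`. The 95% prediction interval for the value of a
*new* Rashomon model uses a t-distribution with `M − 2` degrees of
freedom and scale `√(var(mean) + τ²)`; a variable is significant only
when the lower bound is strictly positive (only positive reliance
indicates importance). `M ≥ 3` is required so the t-distribution has at
least one degree of freedom. Negative bounds and negative means are
reported as-is.

The moment estimator τ² inherits a known weakness: when within-model
variances span orders of magnitude, the handful of near-zero-variance
models dominate `C` and the estimate collapses, shrinking prediction
intervals far below the visible between-model spread. This is why the
default importance estimator injects commensurate Monte-Carlo noise into
every value (see above) rather than using the noiseless exact
marginalisation.

## Ranking and filtering

Within a model, variable `j` beats `k` when
`(x_j − x_k)/√(se_j² + se_k²)` exceeds the one-sided normal quantile at
`α = 0.05` (the two Monte-Carlo errors are independent; no multiplicity
correction — "significantly larger" is directional, and the choice is
exposed as configuration). A variable's rank is one plus the number of
variables with strictly more wins (competition ranking, ties share the
best rank). Aggregating over models gives the rank-frequency matrix, and
`filter_by_rank` selects the models where a variable of interest ranks at
or above a cutoff; the filtered subset is re-pooled through the identical
code path.

## Synthetic data

`SyntheticSpec` draws a latent Gaussian vector with a given correlation
matrix, optionally dichotomises coordinates at per-variable thresholds
(a Gaussian copula for correlated binaries), and draws the outcome from a
logistic model. Effects may sit on the observed predictors (the fitted
model is then correctly specified and recovery of the stated truth is
testable directly) or on the latent coordinates (`latent_coefficients`).
The latent option models *coarsened measurement*: the recorded binary is
a thresholded version of the trait that actually drives the outcome, so a
second variable that is merely correlated with that trait carries genuine
residual signal — a proxy that any well-fitting model can exploit even
though it has no direct effect of its own.

Two scenarios are shipped:

* `compas_like` (default n = 4000, 10% test): six binary predictors in a
  recidivism-style layout. Outcome risk is driven by three latent traits
  (criminal-history 1.3, juvenile-history 0.9, age 0.35 on the log-odds
  scale); the recorded binaries coarsen them, and a null `race_proxy`
  (latent correlation 0.72 with the criminal-history trait, zero effect
  of its own) plays the role of a confounded proxy. By construction the
  proxy earns a sizeable coefficient in the optimal model — typically
  ranking in the top three by mean |SHAP| — while its pooled prediction
  interval across the Rashomon ensemble contains zero: the qualitative
  phenomenon that motivates looking beyond the optimal model, with the
  ground truth known. The scenario parameters were selected so this
  regime holds robustly across seeds and are fixed.
* `mimic_like` (default n = 20,000): 21 continuous ICU-style variables
  with strongly correlated blocks (blood-pressure triplet up to 0.90,
  haematocrit/haemoglobin 0.95, creatinine/urea 0.75, anion-gap/
  bicarbonate −0.55), moderate effects on about half the variables and
  several nulls; several variables exceed the VIF threshold, exercising
  the absolute-value adjustment.

What the generator does *not* emulate: real marginal distributions
(skewness, heavy tails, measurement error), nonlinearity or interactions
in the true risk, and missingness. Passing tests therefore demonstrate
the statistical machinery under a correctly specified-to-mildly-
misspecified logistic world, not robustness to arbitrary real data.

## Numerical choices

* Loss: mean binomial log-loss, probabilities clipped to `[1e-12, 1−1e-12]`
  before logging; clipping never affects a reported digit.
* Baseline value `v(∅)`: loss of the mean predicted probability over the
  full reference sample (deterministic anchor).
* Reference sample: up to 128 training rows (seeded subsample), shared by
  all models of a cloud for comparability; evaluation: the test
  partition, optionally capped by a seeded subsample (200 in the shipped
  workflows — larger test sets cost time roughly linearly and add little
  once Monte-Carlo error dominates).
* Per-model permutation streams derive from the master seed plus the
  model index, keeping clouds reproducible while models stay independent.
* VIF of an (almost) exactly collinear column (R² within 1e-10 of 1) is
  reported infinite, not an error; constant columns are rejected.
* Exact Shapley evaluation is limited to `d ≤ 12` (table size `2^d`).
* The sampler adds `1e-12` to the covariance diagonal before Cholesky to
  absorb benign rank-deficiency; a genuinely indefinite matrix raises.
* Competition ranking breaks win-count ties by sharing the minimal rank;
  pairwise tests use the normal reference (permutation counts are large
  enough that the t-correction would be negligible).
* SVG output embeds no timestamps and uses a fixed hash salt, so
  re-rendering identical data yields byte-identical files.

## Problem sizes in the shipped checks

The test-suite and acceptance-script experiments run the default
`compas_like` conditions (n = 4000, M = 350 models, 40 permutations per
model, 200 evaluation rows, 128 reference rows) for the replication
study, 20 independent replicates for the proxy pattern and 5 for the
acceptance bound; the determinism check uses a reduced configuration
(n = 1200, M = 80, 10 permutations) since it compares bytes, not
statistics. The oracle-equivalence check uses d = 3 with 40 rows and
2,000 orderings.

## Known limitations

* The marginal-distribution approximation biases Shapley values under
  strong correlation; the VIF rule is a pragmatic correction, not a
  conditional-distribution solution.
* DerSimonian–Laird assumes normally distributed true per-model values;
  heavy-tailed or bimodal clouds distort prediction intervals more than
  means. Alternative τ² estimators are out of scope.
* The rejection sampler explores the Rashomon set through Gaussian
  proposals centred at the optimum; it does not guarantee uniform
  coverage of the set, and `u1/u2` need data-dependent tuning.
* Only binary-outcome logistic models are supported; regularised or
  nonlinear model classes and missing-data handling are out of scope.
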