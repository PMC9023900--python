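# shapleyvic

Shapley variable importance clouds for near-optimal logistic models.

## Why

Variable-importance claims are usually made about the single
loss-minimising model. But many models predict almost as well — the
*Rashomon set* — and they can rely on variables very differently: a
variable that looks indispensable to the optimal model may be nearly
irrelevant to other models with practically identical performance. This
matters wherever importance feeds real decisions, e.g. asking whether a
recidivism model truly needs race, or whether an expensive laboratory
test truly drives an ICU mortality score.

`shapleyvic` answers with an *importance cloud*: Shapley-based global
importance (the loss-reduction, SAGE-style value) for every model in a
sampled Rashomon set, pooled into an overall importance with formal
uncertainty. It is aimed at biostatisticians and applied ML researchers
building risk models from tabular clinical or administrative data.

## Method in brief

1. **Fit** the optimal logistic regression `β*` (loss `L*`, covariance `Σ*`).
2. **Sample** near-optimal models: `β_i ~ N(β*, k_i Σ*)` with
   `k_i ~ U(u₁, u₂)`, rejecting models whose mean log-loss exceeds
   `(1 + ε)·L*` (default `ε = 0.05`); keep ~350.
3. **Explain** each model on the test partition: Shapley values
   `φ_j(v_f)` of the loss-reduction value function by permutation
   sampling, with standard errors; where a variable's VIF exceeds 2,
   use `|φ_j|` (collinearity adjustment). This yields the M × d cloud.
4. **Pool** each variable across models by DerSimonian–Laird
   random-effects meta-analysis: between-model variance
   `τ² = max(0, (Q − (M−1))/C)`, overall mean, and a 95% prediction
   interval on `t_{M−2}`; a variable is *overall important* only if the
   interval lies above zero.
5. **Rank and filter**: within-model ranks from one-sided pairwise
   z-tests, rank-frequency tables across the cloud, and re-pooling of
   model subsets where a variable of interest ranks highly.

A conventional mean-|SHAP| ranking of the optimal model is computed
alongside for contrast. Details, defaults and design choices are in
[docs/methods.md](docs/methods.md).

## Worked example

A built-in generator ships a recidivism-style scenario: 4,000 records,
six binary predictors, with a null `race_proxy` that has **no direct
effect** on the outcome but is correlated (latent ρ = 0.72) with the
trait behind `prior_history` — a known-truth stand-in for the classic
race-importance question.

```python
import shapleyvic as sv

data = sv.generate(sv.scenario("compas_like", seed=0))
result = sv.run_workflow(data, sampler_config=sv.SamplerConfig(seed=0), seed=0)

print(result.shap_optimal.head(3).to_string(index=False))
print(result.pooled[["variable", "mean", "pi_lower", "pi_upper",
                     "significant"]].round(4).to_string(index=False))
```

Output:

```
        variable  mean_abs_shap
   prior_history       0.128543
juvenile_history       0.066649
      race_proxy       0.061679
          variable    mean  pi_lower  pi_upper  significant
     prior_history  0.0516    0.0342    0.0690         True
        race_proxy  0.0257   -0.0051    0.0565        False
  juvenile_history  0.0252    0.0128    0.0377         True
       gender_male -0.0007   -0.0128    0.0115        False
         age_young -0.0024   -0.0095    0.0047        False
misdemeanor_charge -0.0025   -0.0103    0.0053        False
```

Read it like this: judged by the optimal model alone (mean |SHAP|), the
proxy looks like the **third most important** variable, close behind the
second. Judged across 350 near-optimal models, its overall importance is
**not significant** — the 95% prediction interval (−0.005, 0.057) contains
zero, because
near-optimal models vary widely in how much they rely on it (they can
substitute the genuinely predictive `prior_history`). The two true
drivers stay significant. That divergence, with the truth known by
construction, is the phenomenon the package exists to expose.

The same pipeline runs from a shell, stage by stage or end to end, with
plain CSV/JSON artifacts and SVG/PNG figures (pooled-importance bars,
loss-coloured violins, rank-frequency table):

```bash
shapleyvic all -c config.json         # simulate→fit→sample→explain→pool→rank→plot
shapleyvic rank -c config.json --filter-variable race_proxy --max-rank 3
```

Any delimited dataset with a binary outcome column can be analysed by
pointing the config's `data` field at a CSV.

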