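"""One-call programmatic workflow: fit, sample, explain, pool.

Convenience wrapper over the individual stages for scripted experiments;
the command-line interface exposes the same sequence with on-disk
artifacts between stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import Dataset, FittedModel, VifReport, compute_vif, fit_optimal_model
from .pooling import pool_cloud
from .sampler import RashomonEnsemble, SamplerConfig, sample_rashomon
from .shapley import ImportanceCloud, compute_cloud, mean_abs_shap

__all__ = ["WorkflowResult", "run_workflow"]


@dataclass
class WorkflowResult:
    data: Dataset
    optimal: FittedModel
    vif: VifReport
    ensemble: RashomonEnsemble
    cloud: ImportanceCloud
    pooled: pd.DataFrame  # one row per variable, descending pooled mean
    shap_optimal: pd.DataFrame | None  # mean |SHAP| ranking of the optimal model


def run_workflow(
    data: Dataset,
    sampler_config: SamplerConfig | None = None,
    vif_threshold: float = 2.0,
    n_permutations: int = 40,
    seed: int = 0,
    reference_size: int = 128,
    evaluation_cap: int | None = 200,
    shap_instances: int | None = 100,
) -> WorkflowResult:
    """Run the SHAP-then-cloud workflow on an in-memory dataset.

    Fits the optimal logistic model, samples the Rashomon ensemble,
    computes the VIF-adjusted importance cloud on the test partition and
    pools it. When ``shap_instances`` is given, the conventional mean
    absolute SHAP ranking of the optimal model is computed on that many
    test rows for contrast with the ensemble-level assessment.
    """
    config = sampler_config or SamplerConfig(seed=seed)
    optimal = fit_optimal_model(data)
    vif = compute_vif(data, threshold=vif_threshold)
    ensemble = sample_rashomon(optimal, data, config)
    cloud = compute_cloud(
        ensemble,
        data,
        vif,
        n_permutations=n_permutations,
        seed=seed,
        reference_size=reference_size,
        evaluation_cap=evaluation_cap,
    )
    pooled = pool_cloud(cloud)

    shap_frame = None
    if shap_instances is not None:
        rng = np.random.default_rng(seed)
        X_train, _ = data.rows("train")
        X_test, _ = data.rows("test")
        ref = X_train[
            rng.choice(
                X_train.shape[0],
                size=min(reference_size, X_train.shape[0]),
                replace=False,
            )
        ]
        mas = mean_abs_shap(
            optimal.coefficients,
            X_test[: min(shap_instances, X_test.shape[0])],
            ref,
            n_permutations=n_permutations,
            seed=seed,
        )
        shap_frame = (
            pd.DataFrame({"variable": data.names, "mean_abs_shap": mas})
            .sort_values("mean_abs_shap", ascending=False)
            .reset_index(drop=True)
        )
    return WorkflowResult(
        data=data, optimal=optimal, vif=vif, ensemble=ensemble,
        cloud=cloud, pooled=pooled, shap_optimal=shap_frame,
    )
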