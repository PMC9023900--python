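"""Random-effects pooling of per-model importance values.

Each Rashomon model is treated as a study reporting an estimate of a
variable's model reliance with a known within-model variance (the squared
Monte-Carlo standard error from the permutation sampler). Because
different near-optimal models genuinely rely on a variable to different
degrees, the true per-model values are modelled as draws from
``N(theta, tau^2)`` and the between-model variance ``tau^2`` is estimated
by the DerSimonian-Laird moment estimator:

    w_m   = 1 / sigma_m^2
    Q     = sum w_m (x_m - xbar_w)^2           (total heterogeneity)
    C     = sum w_m - (sum w_m^2) / (sum w_m)
    tau^2 = max(0, (Q - (M - 1)) / C)

The grand mean is the ``1 / (sigma_m^2 + tau^2)``-weighted average. The
95% prediction interval for the reliance of a *new* model from the
Rashomon set uses a t-distribution with ``M - 2`` degrees of freedom and
scale ``sqrt(var(mean) + tau^2)``; a variable's overall importance is
declared significant only when the lower bound is positive, because only
positive reliance values indicate importance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .shapley import ImportanceCloud

__all__ = ["PooledImportance", "pool_variable", "pool_cloud", "pool_values_frame"]


@dataclass
class PooledImportance:
    """Pooled overall importance of one variable across M models."""

    mean: float
    mean_variance: float
    tau2: float
    q_statistic: float
    scaling_c: float
    pi_lower: float
    pi_upper: float
    significant: bool
    m: int

    def __post_init__(self) -> None:
        if self.mean_variance < 0 or self.tau2 < 0 or self.q_statistic < 0:
            raise ValueError("variance components must be nonnegative")
        if not self.pi_lower < self.pi_upper:
            raise ValueError("degenerate prediction interval")


def pool_variable(values: np.ndarray, variances: np.ndarray) -> PooledImportance:
    """DerSimonian-Laird pooling of one variable's per-model values."""
    x = np.asarray(values, dtype=float)
    v = np.asarray(variances, dtype=float)
    m = x.size
    if m < 3:
        raise ValueError("need at least 3 models (prediction interval df = M - 2)")
    if v.shape != x.shape:
        raise ValueError("values and variances disagree in length")
    if (v <= 0).any():
        raise ValueError("all within-model variances must be positive")

    w = 1.0 / v
    xbar_w = np.sum(w * x) / np.sum(w)
    q = float(np.sum(w * (x - xbar_w) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (m - 1)) / c)

    w_star = 1.0 / (v + tau2)
    mean = float(np.sum(w_star * x) / np.sum(w_star))
    mean_var = float(1.0 / np.sum(w_star))
    t_crit = float(stats.t.ppf(0.975, df=m - 2))
    half = t_crit * np.sqrt(mean_var + tau2)
    lower, upper = mean - half, mean + half
    return PooledImportance(
        mean=mean,
        mean_variance=mean_var,
        tau2=tau2,
        q_statistic=q,
        scaling_c=c,
        pi_lower=lower,
        pi_upper=upper,
        significant=bool(lower > 0),
        m=m,
    )


def pool_cloud(cloud: ImportanceCloud) -> pd.DataFrame:
    """Pool every variable of an importance cloud independently.

    Returns one row per variable, ordered by descending pooled mean — the
    table behind the bar-with-error-bars display.
    """
    if cloud.m < 3:
        raise ValueError("need at least 3 models to pool")
    se = cloud.standard_errors
    if (se == 0).any():
        raise ValueError(
            "zero standard error encountered; increase n_permutations"
        )
    return pool_values_frame(cloud.values, se**2, cloud.names)


def pool_values_frame(
    values: np.ndarray, variances: np.ndarray, names: list[str]
) -> pd.DataFrame:
    """Pool an (M, d) value matrix column by column into a tidy table."""
    records = []
    for j, name in enumerate(names):
        p = pool_variable(values[:, j], variances[:, j])
        records.append(
            {
                "variable": name,
                "mean": p.mean,
                "mean_var": p.mean_variance,
                "tau2": p.tau2,
                "Q": p.q_statistic,
                "pi_lower": p.pi_lower,
                "pi_upper": p.pi_upper,
                "significant": p.significant,
                "m": p.m,
            }
        )
    df = pd.DataFrame(records).sort_values("mean", ascending=False)
    return df.reset_index(drop=True)
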