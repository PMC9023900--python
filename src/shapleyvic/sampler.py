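"""Rejection sampler for nearly optimal ("Rashomon set") logistic models.

A model belongs to the Rashomon set when its empirical loss is within a
factor ``1 + epsilon`` of the optimal model's loss. Coefficient vectors are
proposed from ``N(beta*, k_i * Sigma*)`` with a per-proposal scale
``k_i ~ U(u1, u2)`` and rejected whenever the training loss exceeds the
bound. Mixing over scales is what lets the sample cover the whole loss
range: small ``k`` concentrates near the optimum, large ``k`` probes the
boundary of the set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import Dataset, FittedModel, _loss

__all__ = ["SamplerConfig", "RashomonEnsemble", "sample_rashomon", "tuning_report"]

logger = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    """Tuning knobs of the rejection sampler.

    ``u1``/``u2`` may be given in either order; they are normalised to
    ``(min, max)`` since they bound a uniform distribution.
    """

    epsilon: float = 0.05
    m0: int = 1200
    u1: float = 20.0
    u2: float = 80.0
    final_size: int = 350
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.m0 <= 0 or self.final_size <= 0:
            raise ValueError("m0 and final_size must be positive")
        if self.u1 < 0 or self.u2 < 0:
            raise ValueError("uniform bounds must be nonnegative")
        self.u1, self.u2 = min(self.u1, self.u2), max(self.u1, self.u2)
        if self.m0 < self.final_size:
            warnings.warn(
                "m0 < final_size: the accepted sample cannot reach final_size",
                stacklevel=2,
            )


@dataclass
class RashomonEnsemble:
    """Accepted near-optimal models: coefficients, losses and bookkeeping."""

    coefficients: np.ndarray  # (M, d + 1)
    losses: np.ndarray  # (M,)
    optimal_loss: float
    epsilon: float
    acceptance_count: int
    proposal_count: int

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, float))
        self.losses = np.asarray(self.losses, dtype=float)
        if self.coefficients.shape[0] != self.losses.shape[0]:
            raise ValueError("coefficients and losses disagree on M")
        bound = (1 + self.epsilon) * self.optimal_loss
        if (self.losses > bound + 1e-12).any():
            raise ValueError("ensemble contains a model beyond the loss bound")

    @property
    def m(self) -> int:
        return self.coefficients.shape[0]

    def to_frame(self, names: list[str]) -> pd.DataFrame:
        cols = ["intercept", *names]
        df = pd.DataFrame(self.coefficients, columns=cols)
        df["train_loss"] = self.losses
        return df


def sample_rashomon(
    optimal: FittedModel, data: Dataset, config: SamplerConfig
) -> RashomonEnsemble:
    """Draw a seeded sample of near-optimal models around ``optimal``.

    The optimal model itself is always row 0 of the result so downstream
    comparisons against the loss-minimising model have a fixed reference.
    Accepted proposals beyond ``final_size - 1`` are thinned by uniform
    subsampling without replacement.
    """
    X, y = data.rows("train")
    beta_star = optimal.coefficients
    try:
        chol = np.linalg.cholesky(
            optimal.covariance + 1e-12 * np.eye(len(beta_star))
        )
    except np.linalg.LinAlgError as exc:
        raise ValueError("coefficient covariance is not positive semi-definite") from exc

    rng = np.random.default_rng(config.seed)
    bound = (1 + config.epsilon) * optimal.train_loss
    k = rng.uniform(config.u1, config.u2, size=config.m0)
    z = rng.standard_normal((config.m0, len(beta_star)))
    proposals = beta_star + np.sqrt(k)[:, None] * (z @ chol.T)
    losses = np.array([_loss(b, X, y) for b in proposals])
    accepted = losses <= bound
    n_acc = int(accepted.sum())
    logger.info(
        "rashomon sampling: bound=%.6f, accepted %d / %d proposals (%.1f%%)",
        bound, n_acc, config.m0, 100 * n_acc / config.m0,
    )
    if n_acc == 0 and config.m0 > 0 and not (config.u1 == config.u2 == 0):
        raise RuntimeError(
            "no proposal fell inside the Rashomon set; decrease u1/u2 or "
            "increase m0"
        )

    acc_beta = proposals[accepted]
    acc_loss = losses[accepted]
    n_keep = config.final_size - 1  # row 0 is reserved for the optimal model
    if len(acc_beta) > n_keep:
        idx = rng.choice(len(acc_beta), size=n_keep, replace=False)
        acc_beta, acc_loss = acc_beta[idx], acc_loss[idx]
    elif len(acc_beta) < n_keep:
        warnings.warn(
            f"only {len(acc_beta)} acceptances; ensemble smaller than "
            f"final_size={config.final_size}",
            stacklevel=2,
        )
    return RashomonEnsemble(
        coefficients=np.vstack([beta_star, acc_beta]),
        losses=np.concatenate([[optimal.train_loss], acc_loss]),
        optimal_loss=optimal.train_loss,
        epsilon=config.epsilon,
        acceptance_count=n_acc,
        proposal_count=config.m0,
    )


def tuning_report(ensemble: RashomonEnsemble, n_bins: int = 10) -> pd.DataFrame:
    """Count accepted models per equal-width loss bin.

    The loss range ``[L*, (1 + eps) L*]`` is split into ``n_bins`` bins; a
    well-tuned sampler leaves no bin empty, so the user can iterate on
    ``(m0, u1, u2)`` by inspecting this table. Losses numerically below the
    optimum (fitting tolerance) count toward the first bin.
    """
    if ensemble.m == 0:
        raise ValueError("empty ensemble")
    lo = ensemble.optimal_loss
    hi = (1 + ensemble.epsilon) * ensemble.optimal_loss
    edges = np.linspace(lo, hi, n_bins + 1)
    clipped = np.clip(ensemble.losses, lo, hi)
    counts, _ = np.histogram(clipped, bins=edges)
    rate = ensemble.acceptance_count / max(ensemble.proposal_count, 1)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "acceptance_rate": rate,
        }
    )
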