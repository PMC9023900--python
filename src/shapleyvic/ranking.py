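"""Within-model variable ranking by pairwise significance, and rank filters.

A variable's rank inside one model counts how many of the other ``d - 1``
variables it beats: it "wins" against variable ``k`` when the difference
of their model-reliance values is significantly positive under a normal
test with variance ``se_j^2 + se_k^2`` (the two Monte-Carlo errors are
independent). Ranks use competition ("1224") ordering: tied win counts
share the minimum rank. Aggregating ranks over the cloud gives the
rank-frequency matrix; filtering models where a variable of interest
ranks highly yields a subset that can be re-pooled for a focused look.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .shapley import ImportanceCloud

__all__ = ["RankMatrix", "pairwise_test", "rank_models", "filter_by_rank"]


@dataclass
class RankMatrix:
    """Win counts, ranks and the variable-by-rank frequency table."""

    wins: np.ndarray  # (M, d) int
    ranks: np.ndarray  # (M, d) int, 1 = most important
    alpha: float
    names: list[str]

    def __post_init__(self) -> None:
        self.wins = np.asarray(self.wins, dtype=int)
        self.ranks = np.asarray(self.ranks, dtype=int)
        d = len(self.names)
        if self.wins.shape != self.ranks.shape or self.wins.shape[1] != d:
            raise ValueError("wins/ranks shape mismatch")
        if (self.wins < 0).any() or (self.wins > d - 1).any():
            raise ValueError("win counts must lie in [0, d - 1]")

    @property
    def frequency(self) -> pd.DataFrame:
        """d x d table: rows = variables, columns = ranks 1..d, entries =
        number of models in which the variable attains that rank."""
        d = len(self.names)
        freq = np.zeros((d, d), dtype=int)
        for j in range(d):
            for r in range(1, d + 1):
                freq[j, r - 1] = int(np.sum(self.ranks[:, j] == r))
        return pd.DataFrame(
            freq, index=self.names, columns=[f"rank_{r}" for r in range(1, d + 1)]
        )


def pairwise_test(
    value_j: float,
    se_j: float,
    value_k: float,
    se_k: float,
    alpha: float = 0.05,
) -> bool:
    """One-sided z-test: is value_j significantly larger than value_k?"""
    if se_j <= 0 or se_k <= 0:
        raise ValueError("standard errors must be positive")
    z = (value_j - value_k) / np.hypot(se_j, se_k)
    return bool(z > stats.norm.ppf(1 - alpha))


def rank_models(cloud: ImportanceCloud, alpha: float = 0.05) -> RankMatrix:
    """Rank variables within every model of the cloud.

    Vectorised equivalent of running :func:`pairwise_test` on all ordered
    pairs: wins[m, j] counts variables k with a significantly smaller
    value in model m.
    """
    values = cloud.values  # (M, d)
    se = cloud.standard_errors
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    z_crit = stats.norm.ppf(1 - alpha)
    diff = values[:, :, None] - values[:, None, :]  # (M, d, d), j minus k
    sd = np.sqrt(se[:, :, None] ** 2 + se[:, None, :] ** 2)
    wins = (diff / sd > z_crit).sum(axis=2).astype(int)
    # competition ranking: rank = 1 + number of variables with MORE wins
    ranks = 1 + (wins[:, None, :] > wins[:, :, None]).sum(axis=2).astype(int)
    return RankMatrix(wins=wins, ranks=ranks, alpha=alpha, names=list(cloud.names))


def filter_by_rank(
    rankmatrix: RankMatrix, variable: str, max_rank: int
) -> list[int]:
    """0-based indices of models where ``variable`` ranks ``<= max_rank``."""
    if variable not in rankmatrix.names:
        raise KeyError(f"unknown variable {variable!r}")
    j = rankmatrix.names.index(variable)
    return [int(m) for m in np.nonzero(rankmatrix.ranks[:, j] <= max_rank)[0]]


def subset_cloud(cloud: ImportanceCloud, indices: list[int]) -> ImportanceCloud:
    """Restrict a cloud to the given model indices (for re-pooling)."""
    return ImportanceCloud(
        estimates=[cloud.estimates[i] for i in indices],
        names=list(cloud.names),
        losses=cloud.losses[list(indices)],
    )
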