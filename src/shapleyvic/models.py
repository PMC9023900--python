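"""Dataset container, logistic model fitting, empirical loss and VIF diagnostics.

Everything downstream — the Rashomon sampler, the Shapley engine, the
meta-analytic pooling — consumes the three objects defined here:

* :class:`Dataset` holds the predictor matrix ``X`` (n x d, numeric, with
  categoricals already dummy-encoded), the binary outcome ``y`` and a
  train/test partition.
* :class:`FittedModel` is the loss-minimising logistic regression: its
  coefficient vector ``beta*`` (intercept first), the estimated
  variance-covariance matrix ``Sigma*`` of the coefficients, and its
  training loss ``L*``.
* :class:`VifReport` carries the variance inflation factor of every
  predictor and the collinearity flags (``VIF_j > v``) that drive the
  absolute-value adjustment of importance values.

The empirical loss throughout the package is the *mean* binomial log-loss,
so Rashomon bounds of the form ``(1 + eps) * L*`` are independent of the
sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

__all__ = [
    "Dataset",
    "FittedModel",
    "VifReport",
    "load_dataset",
    "fit_optimal_model",
    "empirical_loss",
    "compute_vif",
]

#: probabilities are clipped to [CLIP, 1 - CLIP] before taking logs; small
#: enough never to alter a reported digit, large enough to keep losses finite.
CLIP = 1e-12

TRAIN, TEST = "train", "test"


@dataclass
class Dataset:
    """Rectangular analysis data: predictors, binary outcome, partition."""

    predictors: np.ndarray  # (n, d) float
    outcome: np.ndarray  # (n,) int in {0, 1}
    names: list[str]
    partition: np.ndarray  # (n,) str, "train" or "test"

    def __post_init__(self) -> None:
        self.predictors = np.asarray(self.predictors, dtype=float)
        self.outcome = np.asarray(self.outcome)
        self.partition = np.asarray(self.partition)
        n, d = self.predictors.shape
        if d < 2:
            raise ValueError(f"need at least 2 predictors, got {d}")
        if n < d + 2:
            raise ValueError(f"need at least d + 2 = {d + 2} rows, got {n}")
        if len(self.names) != d:
            raise ValueError("names do not match predictor columns")
        if len(set(self.names)) != d:
            raise ValueError("duplicate variable names")
        if not np.isin(self.outcome, [0, 1]).all():
            raise ValueError("outcome must contain only 0 and 1")
        if np.isnan(self.predictors).any():
            raise ValueError("predictors contain missing values")
        y_train = self.outcome[self.partition == TRAIN]
        if y_train.size and len(np.unique(y_train)) < 2:
            raise ValueError("outcome has one class in the training partition")

    @property
    def n(self) -> int:
        return self.predictors.shape[0]

    @property
    def d(self) -> int:
        return self.predictors.shape[1]

    def rows(self, partition: str) -> tuple[np.ndarray, np.ndarray]:
        """Predictor matrix and outcome vector of one partition."""
        if partition not in (TRAIN, TEST):
            raise ValueError(f"unknown partition {partition!r}")
        mask = self.partition == partition
        if not mask.any():
            raise ValueError(f"empty partition {partition!r}")
        return self.predictors[mask], self.outcome[mask]

    def to_frame(self, outcome_name: str = "outcome") -> pd.DataFrame:
        df = pd.DataFrame(self.predictors, columns=self.names)
        df[outcome_name] = self.outcome
        return df


@dataclass
class FittedModel:
    """Maximum-likelihood logistic model with its coefficient covariance."""

    coefficients: np.ndarray  # (d + 1,), intercept first
    covariance: np.ndarray  # (d + 1, d + 1)
    train_loss: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if self.train_loss < 0:
            raise ValueError("train_loss must be nonnegative")

    def to_json_dict(self, names: list[str] | None = None) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "covariance": self.covariance.tolist(),
            "train_loss": float(self.train_loss),
            "names": list(names) if names is not None else None,
        }


@dataclass
class VifReport:
    """Variance inflation factors and the strict ``VIF > threshold`` flags."""

    vif: np.ndarray  # (d,), finite values >= 1, np.inf for exact collinearity
    threshold: float
    flagged: np.ndarray = field(init=False)  # (d,) bool

    def __post_init__(self) -> None:
        self.vif = np.asarray(self.vif, dtype=float)
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        finite = np.isfinite(self.vif)
        if (self.vif[finite] < 1 - 1e-9).any():
            raise ValueError("finite VIF values must be >= 1")
        # strict inequality: a variable sitting exactly at the threshold is
        # not adjusted
        self.flagged = self.vif > self.threshold


def load_dataset(
    path,
    outcome_name: str,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> Dataset:
    """Read a delimited text file and partition rows into train/test.

    Rows are assigned by a seeded uniform shuffle so the split is
    reproducible; the test partition holds ``round(n * test_fraction)`` rows.
    Missing cells, non-binary outcomes and duplicate column names are
    rejected outright — the loader never imputes.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    df = pd.read_csv(path)
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column names: {dupes}")
    if outcome_name not in df.columns:
        raise ValueError(f"outcome column {outcome_name!r} not found")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().values)[0]
        raise ValueError(
            f"missing value at row {r}, column {df.columns[c]!r}"
        )
    y = df[outcome_name].to_numpy()
    values = np.unique(y)
    if not np.isin(values, [0, 1]).all():
        raise ValueError(f"outcome {outcome_name!r} is not binary 0/1")
    if len(values) < 2:
        raise ValueError("outcome has one class")
    X = df.drop(columns=[outcome_name])
    if not all(np.issubdtype(t, np.number) for t in X.dtypes):
        bad = [c for c, t in X.dtypes.items() if not np.issubdtype(t, np.number)]
        raise ValueError(f"non-numeric predictor columns: {bad}")

    n = len(df)
    n_test = int(round(n * test_fraction))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    partition = np.full(n, TRAIN, dtype=object)
    partition[order[:n_test]] = TEST
    return Dataset(
        predictors=X.to_numpy(dtype=float),
        outcome=y.astype(int),
        names=list(X.columns),
        partition=partition.astype(str),
    )


def empirical_loss(
    coefficients: np.ndarray, data: Dataset, partition: str = TRAIN
) -> float:
    """Mean binomial log-loss of a coefficient vector on one partition."""
    X, y = data.rows(partition)
    return _loss(coefficients, X, y)


def _loss(coefficients: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    beta = np.asarray(coefficients, dtype=float)
    if beta.shape != (X.shape[1] + 1,):
        raise ValueError(
            f"expected {X.shape[1] + 1} coefficients, got {beta.shape}"
        )
    p = expit(beta[0] + X @ beta[1:])
    p = np.clip(p, CLIP, 1 - CLIP)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def fit_optimal_model(data: Dataset) -> FittedModel:
    """Fit the loss-minimising logistic regression on the training rows.

    The coefficient covariance is the inverse observed information at the
    optimum. Perfect separation (or any other failure to converge) raises;
    regularised fitting is deliberately out of scope.
    """
    X, y = data.rows(TRAIN)
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            result = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises/warns on separation
            raise RuntimeError(
                "logistic fit failed (perfect separation or non-convergence); "
                "regularised fitting is not supported"
            ) from exc
    if not result.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge")
    beta = np.asarray(result.params)
    cov = np.asarray(result.cov_params())
    cov = (cov + cov.T) / 2
    return FittedModel(
        coefficients=beta,
        covariance=cov,
        train_loss=_loss(beta, X, y),
    )


def compute_vif(data: Dataset, threshold: float = 2.0) -> VifReport:
    """Variance inflation factor of each predictor on the training rows.

    ``VIF_j = 1 / (1 - R^2_j)`` from the ordinary linear regression of
    ``X_j`` on all other predictors plus an intercept. The VIF is treated as
    a property of the predictor matrix alone, so one report applies to every
    model in the importance cloud. An (almost) exactly collinear column is
    flagged infinite rather than raising.
    """
    X, _ = data.rows(TRAIN)
    d = X.shape[1]
    if (X.std(axis=0) == 0).any():
        j = int(np.argmin(X.std(axis=0)))
        raise ValueError(f"constant predictor column {data.names[j]!r}")
    vif = np.empty(d)
    for j in range(d):
        others = sm.add_constant(np.delete(X, j, axis=1), has_constant="add")
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        vif[j] = np.inf if r2 > 1 - 1e-10 else 1.0 / (1.0 - r2)
    return VifReport(vif=vif, threshold=threshold)
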