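"""Shapley-based importance: exact evaluation, SAGE sampling, SHAP, VIF rule.

Three value functions share one attribution formula. For a coalition
``S`` of predictors,

* the *global* (SAGE-style) value ``v(S)`` is the reduction in mean
  log-loss over the mean-prediction baseline when the variables in ``S``
  are known and the rest are marginalised out against a background
  ("reference") sample;
* the *local* (SHAP) value ``v(S)`` is the expected prediction for one
  instance when only its ``S``-coordinates are fixed;
* a *custom table* maps every subset to a number and is evaluated exactly —
  the brute-force oracle against which the sampling estimators are checked.

The sampling estimator walks random orderings of the predictors and
averages each variable's marginal contribution as it joins the coalition;
its standard error comes straight from the spread of those contributions.
The VIF rule then converts raw global values into model-reliance values:
variables flagged as strongly collinear keep the magnitude but drop the
sign, since large negative values under collinearity are artifacts of the
marginal-distribution approximation rather than evidence of unimportance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import CLIP, Dataset, VifReport
from .sampler import RashomonEnsemble

__all__ = [
    "CoalitionSpec",
    "ImportanceEstimate",
    "ImportanceCloud",
    "exact_shapley",
    "empirical_value_table",
    "sage_estimate",
    "shap_local",
    "vif_adjust",
    "compute_cloud",
]

MAX_EXACT_D = 12


@dataclass
class CoalitionSpec:
    """Inputs defining a coalition value function.

    ``kind`` is one of ``global_sage`` (needs ``reference`` and
    ``evaluation``), ``local_shap`` (needs ``reference``) or
    ``custom_table`` (needs ``custom_table`` covering all ``2^d`` subsets,
    keyed by frozensets of 0-based variable indices).
    """

    kind: str
    reference: np.ndarray | None = None  # (r, d) background predictor rows
    evaluation: tuple[np.ndarray, np.ndarray] | None = None  # (X_eval, y_eval)
    custom_table: dict[frozenset, float] | None = None
    n_players: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("global_sage", "local_shap", "custom_table"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "custom_table":
            if self.custom_table is None:
                raise ValueError("custom_table kind requires a table")
            if self.n_players is None:
                players: set[int] = set()
                for s in self.custom_table:
                    players |= set(s)
                self.n_players = (max(players) + 1) if players else 0
        elif self.reference is None:
            raise ValueError(f"{self.kind} requires a reference sample")
        if self.kind == "global_sage" and self.evaluation is None:
            raise ValueError("global_sage requires evaluation rows")


@dataclass
class ImportanceEstimate:
    """Per-variable importance of one model, with Monte-Carlo uncertainty."""

    values: np.ndarray  # (d,)
    standard_errors: np.ndarray  # (d,), >= 0
    adjusted: np.ndarray  # (d,) bool, True where the VIF rule was applied
    model_loss: float
    n_permutations: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        self.adjusted = np.asarray(self.adjusted, dtype=bool)
        if (self.standard_errors < 0).any():
            raise ValueError("standard errors must be nonnegative")
        if (self.values[self.adjusted] < 0).any():
            raise ValueError("adjusted values must be nonnegative")


@dataclass
class ImportanceCloud:
    """M x d matrix of model-reliance values across a Rashomon ensemble."""

    estimates: list[ImportanceEstimate]
    names: list[str]
    losses: np.ndarray  # (M,) training losses copied from the ensemble

    def __post_init__(self) -> None:
        d = len(self.names)
        for est in self.estimates:
            if est.values.shape != (d,):
                raise ValueError("ragged cloud: estimate does not match names")
        self.losses = np.asarray(self.losses, dtype=float)
        if len(self.losses) != len(self.estimates):
            raise ValueError("losses do not match estimates")

    @property
    def m(self) -> int:
        return len(self.estimates)

    @property
    def values(self) -> np.ndarray:
        return np.array([e.values for e in self.estimates])

    @property
    def standard_errors(self) -> np.ndarray:
        return np.array([e.standard_errors for e in self.estimates])

    def to_frame(self) -> pd.DataFrame:
        """Long format: model_id, variable, value, se, adjusted, model_loss."""
        rows = []
        for m, est in enumerate(self.estimates):
            for j, name in enumerate(self.names):
                rows.append(
                    {
                        "model_id": m,
                        "variable": name,
                        "value": est.values[j],
                        "se": est.standard_errors[j],
                        "adjusted": bool(est.adjusted[j]),
                        "model_loss": self.losses[m],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ImportanceCloud":
        names = list(df[df.model_id == df.model_id.min()].variable)
        estimates, losses = [], []
        for m, grp in df.groupby("model_id", sort=True):
            grp = grp.set_index("variable").loc[names]
            estimates.append(
                ImportanceEstimate(
                    values=grp.value.to_numpy(),
                    standard_errors=grp.se.to_numpy(),
                    adjusted=grp.adjusted.to_numpy(dtype=bool),
                    model_loss=float(grp.model_loss.iloc[0]),
                    n_permutations=0,
                )
            )
            losses.append(float(grp.model_loss.iloc[0]))
        return cls(estimates=estimates, names=names, losses=np.array(losses))


def exact_shapley(spec: CoalitionSpec) -> np.ndarray:
    """Exact Shapley values of an explicitly tabulated value function.

    phi_j = (1/d) * sum over S not containing j of
    C(d-1, |S|)^-1 * [w(S + j) - w(S)], which equals the average marginal
    contribution of j over all d! orderings. Requires the full 2^d table.
    """
    if spec.custom_table is None:
        raise ValueError("exact_shapley needs a custom_table spec")
    d = spec.n_players or 0
    if d > MAX_EXACT_D:
        raise ValueError(f"exact evaluation limited to d <= {MAX_EXACT_D}")
    table = spec.custom_table
    missing = [
        set(s)
        for size in range(d + 1)
        for s in map(frozenset, combinations(range(d), size))
        if s not in table
    ]
    if missing:
        raise ValueError(f"incomplete coalition table; missing subsets: {missing}")
    phi = np.zeros(d)
    for j in range(d):
        rest = [i for i in range(d) if i != j]
        for size in range(d):
            weight = 1.0 / (d * comb(d - 1, size))
            for s in combinations(rest, size):
                s = frozenset(s)
                phi[j] += weight * (table[s | {j}] - table[s])
    return phi


def shapley_by_enumeration(table: dict[frozenset, float], d: int) -> np.ndarray:
    """Average marginal contribution over all d! orderings (slow oracle)."""
    phi = np.zeros(d)
    n = 0
    for order in permutations(range(d)):
        coalition: frozenset = frozenset()
        for j in order:
            phi[j] += table[coalition | {j}] - table[coalition]
            coalition = coalition | {j}
        n += 1
    return phi / n


def _mixed_loss(
    a: np.ndarray, b: np.ndarray, y: np.ndarray
) -> float:
    """Mean log-loss of marginalised predictions.

    ``a`` holds each evaluation row's in-coalition linear predictor
    (intercept included), ``b`` each reference row's out-of-coalition part;
    the prediction for an evaluation row is the reference-average of
    ``expit(a_i + b_r)``.
    """
    p = expit(a[:, None] + b[None, :]).mean(axis=1)
    p = np.clip(p, CLIP, 1 - CLIP)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _mixed_prediction(a: float, b: np.ndarray) -> float:
    return float(expit(a + b).mean())


def sage_estimate(
    coefficients: np.ndarray,
    spec: CoalitionSpec,
    n_permutations: int = 40,
    seed: int = 0,
    marginal_batch: int | None = 64,
    converge_tol: float | None = None,
    max_permutations: int = 2048,
) -> ImportanceEstimate:
    """Global Shapley importance of one logistic model, by permutation sampling.

    For each sampled ordering of the d variables, variables join the
    conditioning coalition one at a time; a variable's contribution is the
    drop in mean evaluation loss when it joins, with out-of-coalition
    variables marginalised against the reference sample. Values sum to the
    loss of the mean prediction minus the full-model loss, up to
    Monte-Carlo error.

    ``marginal_batch`` controls how the marginal expectation is taken. With
    an integer ``q``, each coalition evaluation draws a fresh batch of ``q``
    reference rows (with replacement) and averages predictions over it;
    successive evaluations use independent batches, so every variable's
    contribution carries a comparable Monte-Carlo error — the property the
    downstream inverse-variance pooling relies on. With ``None`` the full
    reference sample is used deterministically, which is the low-noise
    choice for small-d comparisons against exhaustive enumeration (its
    standard errors then only reflect the sampling of orderings).

    When ``converge_tol`` is given, batches of ``n_permutations`` orderings
    are added until ``max_j se_j / max_k |phi_k|`` falls below it (or the
    permutation cap is hit).
    """
    if spec.kind != "global_sage":
        raise ValueError("sage_estimate needs a global_sage spec")
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations for a standard error")
    beta = np.asarray(coefficients, dtype=float)
    X_eval, y_eval = spec.evaluation
    X_ref = spec.reference
    d = X_eval.shape[1]
    n_ref = X_ref.shape[0]
    if beta.shape != (d + 1,):
        raise ValueError(f"expected {d + 1} coefficients, got {beta.shape}")
    if marginal_batch is not None and marginal_batch >= n_ref:
        marginal_batch = None
    rng = np.random.default_rng(seed)

    b_full = X_ref @ beta[1:]  # every variable marginalised

    def coalition_loss(a: np.ndarray, b: np.ndarray) -> float:
        if marginal_batch is None:
            return _mixed_loss(a, b, y_eval)
        idx = rng.integers(0, n_ref, size=marginal_batch)
        return _mixed_loss(a, b[idx], y_eval)

    # baseline: the mean prediction over the full reference sample, scored
    # on the evaluation outcomes (deterministic anchor of the value scale)
    p0 = float(np.clip(expit(beta[0] + b_full).mean(), CLIP, 1 - CLIP))
    base_loss = float(
        -np.mean(y_eval * np.log(p0) + (1 - y_eval) * np.log1p(-p0))
    )

    contribs: list[np.ndarray] = []
    while True:
        batch = np.empty((n_permutations, d))
        for t in range(n_permutations):
            order = rng.permutation(d)
            a = np.full(X_eval.shape[0], beta[0])
            b = b_full.copy()
            # re-estimate the empty-coalition loss with batch noise so the
            # first entrant is not favoured by a noiseless anchor
            prev = (
                base_loss
                if marginal_batch is None
                else coalition_loss(a, b)
            )
            for j in order:
                a = a + X_eval[:, j] * beta[j + 1]
                b = b - X_ref[:, j] * beta[j + 1]
                cur = coalition_loss(a, b)
                batch[t, j] = prev - cur
                prev = cur
        contribs.append(batch)
        stacked = np.vstack(contribs)
        phi = stacked.mean(axis=0)
        se = stacked.std(axis=0, ddof=1) / np.sqrt(stacked.shape[0])
        if converge_tol is None or stacked.shape[0] >= max_permutations:
            break
        scale = np.max(np.abs(phi))
        if scale > 0 and np.max(se) / scale < converge_tol:
            break

    full_loss = _mixed_loss(beta[0] + X_eval @ beta[1:], np.zeros(1), y_eval)
    return ImportanceEstimate(
        values=phi,
        standard_errors=se,
        adjusted=np.zeros(d, dtype=bool),
        model_loss=full_loss,
        n_permutations=stacked.shape[0],
    )


def empirical_value_table(
    coefficients: np.ndarray,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    X_ref: np.ndarray,
) -> dict[frozenset, float]:
    """Enumerate v(S) = base_loss - loss(S) for every subset (d <= 12).

    This is the exhaustive global value function the sampling estimator
    approximates; feeding it to :func:`exact_shapley` yields the exact
    target of :func:`sage_estimate`.
    """
    beta = np.asarray(coefficients, dtype=float)
    d = X_eval.shape[1]
    if d > MAX_EXACT_D:
        raise ValueError(f"enumeration limited to d <= {MAX_EXACT_D}")
    b_full = X_ref @ beta[1:]
    p0 = float(np.clip(expit(beta[0] + b_full).mean(), CLIP, 1 - CLIP))
    base_loss = float(
        -np.mean(y_eval * np.log(p0) + (1 - y_eval) * np.log1p(-p0))
    )
    table: dict[frozenset, float] = {}
    for size in range(d + 1):
        for s in combinations(range(d), size):
            mask = np.zeros(d, dtype=bool)
            mask[list(s)] = True
            a = beta[0] + X_eval[:, mask] @ beta[1:][mask]
            b = X_ref[:, ~mask] @ beta[1:][~mask]
            table[frozenset(s)] = base_loss - _mixed_loss(a, b, y_eval)
    return table


def shap_local(
    coefficients: np.ndarray,
    spec: CoalitionSpec,
    instance: np.ndarray,
    n_permutations: int = 40,
    seed: int = 0,
) -> np.ndarray:
    """Shapley attribution of one instance's prediction (SHAP values).

    Same permutation machinery as :func:`sage_estimate` but the value of a
    coalition is the instance's expected prediction with only its
    coalition coordinates fixed. Values sum to prediction(instance) minus
    the mean reference prediction. Standard errors are not reported:
    only global values feed statistical inference.
    """
    if spec.kind != "local_shap":
        raise ValueError("shap_local needs a local_shap spec")
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    beta = np.asarray(coefficients, dtype=float)
    x = np.asarray(instance, dtype=float)
    X_ref = spec.reference
    d = X_ref.shape[1]
    if beta.shape != (d + 1,):
        raise ValueError(f"expected {d + 1} coefficients, got {beta.shape}")
    rng = np.random.default_rng(seed)
    b_full = X_ref @ beta[1:]
    base_value = _mixed_prediction(beta[0], b_full)

    contrib = np.zeros((n_permutations, d))
    for t in range(n_permutations):
        order = rng.permutation(d)
        a = beta[0]
        b = b_full.copy()
        prev = base_value
        for j in order:
            a = a + x[j] * beta[j + 1]
            b = b - X_ref[:, j] * beta[j + 1]
            cur = _mixed_prediction(a, b)
            contrib[t, j] = cur - prev
            prev = cur
    return contrib.mean(axis=0)


def mean_abs_shap(
    coefficients: np.ndarray,
    X_eval: np.ndarray,
    X_ref: np.ndarray,
    n_permutations: int = 40,
    seed: int = 0,
) -> np.ndarray:
    """Mean absolute SHAP value over evaluation rows.

    The conventional heuristic global ranking for a single (optimal) model,
    against which the ensemble-level assessment is contrasted.
    """
    spec = CoalitionSpec(kind="local_shap", reference=X_ref)
    totals = np.zeros(X_eval.shape[1])
    for i, x in enumerate(X_eval):
        phi = shap_local(
            coefficients, spec, x, n_permutations=n_permutations,
            seed=(seed + i) % 2**31,
        )
        totals += np.abs(phi)
    return totals / X_eval.shape[0]


def vif_adjust(raw: ImportanceEstimate, vif: VifReport) -> ImportanceEstimate:
    """Apply the collinearity rule: |value| where VIF > threshold (strict)."""
    if raw.values.shape != vif.vif.shape:
        raise ValueError("estimate and VIF report disagree on d")
    values = np.where(vif.flagged, np.abs(raw.values), raw.values)
    return ImportanceEstimate(
        values=values,
        standard_errors=raw.standard_errors.copy(),
        adjusted=vif.flagged.copy(),
        model_loss=raw.model_loss,
        n_permutations=raw.n_permutations,
    )


def compute_cloud(
    ensemble: RashomonEnsemble,
    data: Dataset,
    vif: VifReport,
    n_permutations: int = 40,
    seed: int = 0,
    reference_size: int = 128,
    evaluation_cap: int | None = None,
    marginal_batch: int | None = 64,
) -> ImportanceCloud:
    """VIF-adjusted global importance of every model in the ensemble.

    Evaluation rows come from the test partition (optionally capped by a
    seeded subsample), the reference sample is a seeded subsample of up to
    ``reference_size`` training rows shared by all models, and each model
    gets its own permutation stream derived from the master seed.
    """
    if ensemble.m == 0:
        raise ValueError("empty ensemble")
    X_train, _ = data.rows("train")
    X_test, y_test = data.rows("test")
    rng = np.random.default_rng(seed)
    if X_train.shape[0] > reference_size:
        idx = rng.choice(X_train.shape[0], size=reference_size, replace=False)
        X_ref = X_train[idx]
    else:
        X_ref = X_train
    if evaluation_cap is not None and X_test.shape[0] > evaluation_cap:
        idx = rng.choice(X_test.shape[0], size=evaluation_cap, replace=False)
        X_test, y_test = X_test[idx], y_test[idx]

    spec = CoalitionSpec(
        kind="global_sage", reference=X_ref, evaluation=(X_test, y_test)
    )
    estimates = []
    for i, beta in enumerate(ensemble.coefficients):
        raw = sage_estimate(
            beta, spec, n_permutations=n_permutations,
            seed=(seed + 1 + i) % 2**31, marginal_batch=marginal_batch,
        )
        estimates.append(vif_adjust(raw, vif))
    return ImportanceCloud(
        estimates=estimates, names=list(data.names),
        losses=ensemble.losses.copy(),
    )
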