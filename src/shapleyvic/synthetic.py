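"""Synthetic logistic-regression data with controlled correlation structure.

A latent Gaussian vector with a specified correlation matrix drives both
the predictors (optionally dichotomised at per-variable thresholds — a
Gaussian copula for correlated binaries) and, through a logistic link,
the binary outcome. Effects can be placed on the *observed* predictors,
on the *latent* Gaussians, or both:

* observed effects make the fitted model correctly specified, so the
  maximum-likelihood fit recovers the stated truth;
* latent effects on dichotomised variables emulate coarsened measurements
  (the recorded binary is a thresholded version of the trait that actually
  drives the outcome). A variable with zero effect of its own but a high
  latent correlation with such a coarsened driver then behaves like a
  proxy: genuinely useful to any fitted model, yet with no direct effect
  on the outcome.

Two shipped scenarios mirror the shapes of the method's two motivating
applications: a six-binary-variable recidivism-style problem with a null
"race proxy" riding on a strong coarsened predictor, and a 21-variable
ICU-mortality-style problem with strongly correlated vital-sign and
laboratory blocks plus several null variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .models import Dataset, TEST, TRAIN

__all__ = ["SyntheticSpec", "generate", "scenario", "implied_prevalence"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    n: int
    d: int
    coefficients: np.ndarray  # (d + 1,) observed-scale truth, intercept first
    correlation: np.ndarray  # (d, d) positive-definite, unit diagonal
    binarize: np.ndarray | None = None  # (d,) thresholds; NaN keeps continuous
    latent_coefficients: np.ndarray | None = None  # (d,) effects of latents
    names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.coefficients.shape != (self.d + 1,):
            raise ValueError("coefficients must have length d + 1")
        if self.correlation.shape != (self.d, self.d):
            raise ValueError("correlation must be d x d")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation must have unit diagonal")
        try:
            np.linalg.cholesky(self.correlation)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive-definite") from exc
        if self.binarize is not None:
            self.binarize = np.asarray(self.binarize, dtype=float)
            if self.binarize.shape != (self.d,):
                raise ValueError("binarize thresholds must have length d")
        if self.latent_coefficients is not None:
            self.latent_coefficients = np.asarray(
                self.latent_coefficients, dtype=float
            )
            if self.latent_coefficients.shape != (self.d,):
                raise ValueError("latent_coefficients must have length d")
        if self.names is None:
            self.names = [f"X{j + 1}" for j in range(self.d)]

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "d": self.d,
            "coefficients": self.coefficients.tolist(),
            "correlation": self.correlation.tolist(),
            "binarize": None if self.binarize is None else self.binarize.tolist(),
            "latent_coefficients": (
                None
                if self.latent_coefficients is None
                else self.latent_coefficients.tolist()
            ),
            "names": self.names,
            "seed": self.seed,
        }


def _draw(spec: SyntheticSpec, n: int, rng: np.random.Generator):
    """Latent draws, observed predictors and outcome probabilities."""
    chol = np.linalg.cholesky(spec.correlation)
    z = rng.standard_normal((n, spec.d)) @ chol.T
    x = z.copy()
    if spec.binarize is not None:
        cut = ~np.isnan(spec.binarize)
        x[:, cut] = (z[:, cut] > spec.binarize[cut]).astype(float)
    eta = spec.coefficients[0] + x @ spec.coefficients[1:]
    if spec.latent_coefficients is not None:
        eta = eta + z @ spec.latent_coefficients
    return z, x, expit(eta)


def generate(spec: SyntheticSpec, test_fraction: float = 0.1) -> Dataset:
    """Materialise a :class:`~shapleyvic.models.Dataset` from a spec."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    _, x, p = _draw(spec, spec.n, rng)
    y = (rng.uniform(size=spec.n) < p).astype(int)
    n_test = int(round(spec.n * test_fraction))
    order = rng.permutation(spec.n)
    partition = np.full(spec.n, TRAIN, dtype=object)
    partition[order[:n_test]] = TEST
    return Dataset(
        predictors=x,
        outcome=y,
        names=list(spec.names),
        partition=partition.astype(str),
    )


def implied_prevalence(
    spec: SyntheticSpec, n_mc: int = 200_000, seed: int = 12345
) -> float:
    """Monte-Carlo outcome prevalence implied by the generating truth."""
    rng = np.random.default_rng(seed)
    _, _, p = _draw(spec, n_mc, rng)
    return float(p.mean())


def _compas_like(n: int, seed: int) -> SyntheticSpec:
    d = 6
    names = [
        "age_young",
        "gender_male",
        "race_proxy",
        "prior_history",
        "juvenile_history",
        "misdemeanor_charge",
    ]
    corr = np.eye(d)
    # the null proxy rides on the latent trait behind prior criminal history
    i_proxy, i_prior = names.index("race_proxy"), names.index("prior_history")
    corr[i_proxy, i_prior] = corr[i_prior, i_proxy] = 0.72
    thresholds = np.array([1.0, -0.85, 0.0, 0.5, 1.1, 0.4])
    coefficients = np.array([-0.6, 0, 0, 0, 0, 0, 0], dtype=float)
    # outcome driven by the latent traits: the recorded binaries are
    # coarsened, so the proxy carries genuine residual signal
    latent = np.zeros(d)
    latent[names.index("age_young")] = 0.35
    latent[i_prior] = 1.3
    latent[names.index("juvenile_history")] = 0.9
    return SyntheticSpec(
        n=n,
        d=d,
        coefficients=coefficients,
        correlation=corr,
        binarize=thresholds,
        latent_coefficients=latent,
        names=names,
        seed=seed,
    )


def _mimic_like(n: int, seed: int) -> SyntheticSpec:
    names = [
        "age",
        "heart_rate",
        "sbp",
        "dbp",
        "map",
        "resp_rate",
        "temperature",
        "spo2",
        "glucose",
        "anion_gap",
        "bicarbonate",
        "creatinine",
        "chloride",
        "hematocrit",
        "hemoglobin",
        "lactate",
        "platelet",
        "potassium",
        "bun",
        "sodium",
        "wbc",
    ]
    d = len(names)
    idx = {v: j for j, v in enumerate(names)}
    corr = np.eye(d)

    def link(a: str, b: str, rho: float) -> None:
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho

    # blood-pressure triplet, red-cell pair, renal pair, acid-base pair
    link("sbp", "dbp", 0.72)
    link("sbp", "map", 0.88)
    link("dbp", "map", 0.90)
    link("hematocrit", "hemoglobin", 0.95)
    link("creatinine", "bun", 0.75)
    link("anion_gap", "bicarbonate", -0.55)
    link("chloride", "sodium", 0.60)

    beta = np.zeros(d + 1)
    beta[0] = -2.6
    effects = {
        "age": 0.45,
        "heart_rate": 0.30,
        "sbp": -0.20,
        "map": -0.25,
        "resp_rate": 0.40,
        "anion_gap": 0.35,
        "bicarbonate": -0.20,
        "creatinine": 0.25,
        "bun": 0.30,
        "lactate": 0.30,
        "wbc": 0.20,
        "spo2": -0.15,
        "hemoglobin": -0.15,
    }
    for v, b in effects.items():
        beta[idx[v] + 1] = b
    return SyntheticSpec(
        n=n,
        d=d,
        coefficients=beta,
        correlation=corr,
        names=names,
        seed=seed,
    )


def scenario(name: str, n: int | None = None, seed: int = 0) -> SyntheticSpec:
    """Shipped study-shaped scenarios: ``compas_like`` or ``mimic_like``."""
    if name == "compas_like":
        return _compas_like(n if n is not None else 4000, seed)
    if name == "mimic_like":
        return _mimic_like(n if n is not None else 20_000, seed)
    raise ValueError(f"unknown scenario {name!r}")
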