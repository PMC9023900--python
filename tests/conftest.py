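import numpy as np
import pytest

import shapleyvic as sv


@pytest.fixture(scope="session")
def small_data() -> sv.Dataset:
    """Small independent-predictor logistic dataset, fixed seed."""
    spec = sv.SyntheticSpec(
        n=200,
        d=3,
        coefficients=np.array([0.2, 0.9, -0.6, 0.0]),
        correlation=np.eye(3),
        seed=1,
    )
    return sv.generate(spec, test_fraction=0.25)


@pytest.fixture(scope="session")
def small_optimal(small_data) -> sv.FittedModel:
    return sv.fit_optimal_model(small_data)


@pytest.fixture()
def d3_table() -> dict:
    """Three-player coalition table with known Shapley values (1.5, 1.5, 0)."""
    return {
        frozenset(): 0.0,
        frozenset({0}): 1.0,
        frozenset({1}): 1.0,
        frozenset({2}): 0.0,
        frozenset({0, 1}): 3.0,
        frozenset({0, 2}): 1.0,
        frozenset({1, 2}): 1.0,
        frozenset({0, 1, 2}): 3.0,
    }


def make_cloud(values, ses, losses=None, names=None) -> sv.ImportanceCloud:
    """Assemble an ImportanceCloud from explicit value / SE matrices."""
    values = np.asarray(values, dtype=float)
    ses = np.asarray(ses, dtype=float)
    m, d = values.shape
    names = names or [f"V{j + 1}" for j in range(d)]
    losses = np.asarray(losses if losses is not None else np.full(m, 0.5))
    estimates = [
        sv.ImportanceEstimate(
            values=values[i],
            standard_errors=ses[i],
            adjusted=np.zeros(d, dtype=bool),
            model_loss=float(losses[i]),
            n_permutations=10,
        )
        for i in range(m)
    ]
    return sv.ImportanceCloud(estimates=estimates, names=names, losses=losses)


@pytest.fixture()
def cloud_factory():
    return make_cloud
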