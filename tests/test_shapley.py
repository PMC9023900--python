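import numpy as np
import pytest
from scipy.special import expit

import shapleyvic as sv
from shapleyvic.shapley import CoalitionSpec, shapley_by_enumeration


def _subsets(d):
    from itertools import combinations

    for size in range(d + 1):
        yield from map(frozenset, combinations(range(d), size))


class TestExactShapley:
    def test_known_three_player_game(self, d3_table):
        spec = CoalitionSpec(kind="custom_table", custom_table=d3_table)
        phi = sv.exact_shapley(spec)
        np.testing.assert_allclose(phi, [1.5, 1.5, 0.0], atol=1e-14)
        # cross-check against the all-orderings brute force
        np.testing.assert_allclose(phi, shapley_by_enumeration(d3_table, 3), atol=1e-14)
        # efficiency: values sum to w(D) - w(empty)
        assert phi.sum() == pytest.approx(3.0, abs=1e-14)

    def test_constant_game_has_dummy_players(self):
        table = {s: 4.2 for s in _subsets(4)}
        phi = sv.exact_shapley(CoalitionSpec(kind="custom_table", custom_table=table))
        np.testing.assert_allclose(phi, 0.0, atol=1e-14)

    def test_additive_game_returns_per_player_worth(self):
        c = np.array([0.3, -1.2, 2.0, 0.0])
        table = {s: sum(c[j] for j in s) for s in _subsets(4)}
        phi = sv.exact_shapley(CoalitionSpec(kind="custom_table", custom_table=table))
        np.testing.assert_allclose(phi, c, atol=1e-12)

    def test_incomplete_table_lists_missing_subsets(self, d3_table):
        del d3_table[frozenset({0, 2})]
        spec = CoalitionSpec(kind="custom_table", custom_table=d3_table,
                             n_players=3)
        with pytest.raises(ValueError, match="missing"):
            sv.exact_shapley(spec)


def _sage_problem(seed=7, n=40, beta=(0.1, 0.7, -0.4, 0.05)):
    spec = sv.SyntheticSpec(
        n=n, d=3, coefficients=np.array([0.2, 0.8, -0.5, 0.0]),
        correlation=np.eye(3), seed=seed,
    )
    data = sv.generate(spec, test_fraction=0.5)
    X, y = data.predictors, data.outcome
    return np.asarray(beta), X, y


class TestSageEstimate:
    def test_null_model_attributes_nothing(self):
        beta, X, y = _sage_problem(beta=(0.3, 0.0, 0.0, 0.0))
        spec = CoalitionSpec(kind="global_sage", reference=X, evaluation=(X, y))
        est = sv.sage_estimate(beta, spec, n_permutations=50, seed=1,
                               marginal_batch=None)
        np.testing.assert_allclose(est.values, 0.0, atol=1e-12)

    def test_ignored_variable_gets_no_importance(self):
        # X3 independent of the others with coefficient 0
        beta, X, y = _sage_problem(beta=(0.1, 0.7, -0.4, 0.0))
        spec = CoalitionSpec(kind="global_sage", reference=X, evaluation=(X, y))
        est = sv.sage_estimate(beta, spec, n_permutations=100, seed=2)
        assert abs(est.values[2]) <= 3 * max(est.standard_errors[2], 1e-12)

    def test_matches_enumeration_oracle(self):
        # exhaustive 2^3-coalition table with full marginalisation is the
        # exact target; the permutation sampler must agree within 3 SEs
        beta, X, y = _sage_problem()
        table = sv.empirical_value_table(beta, X, y, X)
        exact = sv.exact_shapley(
            CoalitionSpec(kind="custom_table", custom_table=table)
        )
        spec = CoalitionSpec(kind="global_sage", reference=X, evaluation=(X, y))
        est = sv.sage_estimate(beta, spec, n_permutations=2000, seed=3,
                               marginal_batch=None)
        dev = np.abs(est.values - exact)
        assert np.all(dev <= 3 * np.maximum(est.standard_errors, 1e-12))

    def test_batched_marginalisation_is_close_to_exact_target(self):
        # sampling the marginal expectation adds a small convexity bias
        # (loss of a batch-averaged prediction vs the full average) on top
        # of Monte-Carlo noise; it must stay well below the value scale
        beta, X, y = _sage_problem()
        table = sv.empirical_value_table(beta, X, y, X)
        exact = sv.exact_shapley(
            CoalitionSpec(kind="custom_table", custom_table=table)
        )
        spec = CoalitionSpec(kind="global_sage", reference=X, evaluation=(X, y))
        est = sv.sage_estimate(beta, spec, n_permutations=2000, seed=3,
                               marginal_batch=16)
        dev = np.abs(est.values - exact)
        assert np.all(dev <= 3 * est.standard_errors + 0.004)

    def test_efficiency_sums_to_total_value(self):
        beta, X, y = _sage_problem()
        table = sv.empirical_value_table(beta, X, y, X)
        v_full = table[frozenset({0, 1, 2})]
        spec = CoalitionSpec(kind="global_sage", reference=X, evaluation=(X, y))
        est = sv.sage_estimate(beta, spec, n_permutations=500, seed=4,
                               marginal_batch=16)
        mc_se = np.sqrt(np.sum(est.standard_errors**2))
        assert abs(est.values.sum() - v_full) <= 4 * max(mc_se, 1e-12)

    def test_duplicated_symmetric_predictors_agree(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=120)
        X = np.column_stack([x, x, rng.normal(size=120)])
        y = (rng.uniform(size=120) < expit(x)).astype(int)
        beta = np.array([0.0, 0.5, 0.5, 0.2])
        spec = CoalitionSpec(kind="global_sage", reference=X, evaluation=(X, y))
        est = sv.sage_estimate(beta, spec, n_permutations=600, seed=5,
                               marginal_batch=16)
        se = np.hypot(est.standard_errors[0], est.standard_errors[1])
        assert abs(est.values[0] - est.values[1]) <= 4 * se

    def test_too_few_permutations_rejected(self):
        beta, X, y = _sage_problem()
        spec = CoalitionSpec(kind="global_sage", reference=X, evaluation=(X, y))
        with pytest.raises(ValueError, match="permutations"):
            sv.sage_estimate(beta, spec, n_permutations=1)


class TestShapLocal:
    def test_constant_model_attributes_nothing(self):
        X_ref = np.random.default_rng(0).normal(size=(50, 2))
        spec = CoalitionSpec(kind="local_shap", reference=X_ref)
        phi = sv.shap_local(np.array([0.4, 0.0, 0.0]), spec,
                            np.array([1.0, -1.0]), n_permutations=20, seed=0)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_efficiency_for_one_instance(self):
        rng = np.random.default_rng(1)
        X_ref = rng.normal(size=(300, 2))
        beta = np.array([0.3, 1.2, -0.7])
        x = np.array([0.5, -1.0])
        phi = sv.shap_local(beta, CoalitionSpec(kind="local_shap", reference=X_ref),
                            x, n_permutations=400, seed=2)
        target = expit(beta[0] + x @ beta[1:]) - expit(
            beta[0] + X_ref @ beta[1:]
        ).mean()
        assert phi.sum() == pytest.approx(target, abs=1e-9)

    def test_additive_linear_closed_form(self):
        # with d = 2 and independent reference columns, the attribution of
        # each variable is close to the one-variable marginalised effect
        rng = np.random.default_rng(3)
        X_ref = rng.normal(size=(4000, 2))
        beta = np.array([0.0, 0.9, -0.6])
        x = np.array([1.2, 0.4])
        phi = sv.shap_local(beta, CoalitionSpec(kind="local_shap", reference=X_ref),
                            x, n_permutations=200, seed=4)
        # enumeration oracle over both orderings with the same reference
        b = X_ref @ beta[1:]
        def v(mask):
            a = beta[0] + sum(x[j] * beta[j + 1] for j in range(2) if mask[j])
            out = sum(X_ref[:, j] * beta[j + 1] for j in range(2) if not mask[j])
            out = out if isinstance(out, np.ndarray) else np.zeros(len(X_ref))
            return expit(a + out).mean()
        v00, v10, v01, v11 = (v(m) for m in ([0, 0], [1, 0], [0, 1], [1, 1]))
        oracle = np.array(
            [((v10 - v00) + (v11 - v01)) / 2, ((v01 - v00) + (v11 - v10)) / 2]
        )
        # the sampler draws orderings, so the two marginal contributions mix
        # with multinomial weights: allow a few Monte-Carlo standard errors
        se = abs((v10 - v00) - (v11 - v01)) / (2 * np.sqrt(200))
        np.testing.assert_allclose(phi, oracle, atol=4 * se)


class TestVifAdjust:
    def _estimate(self, values):
        values = np.asarray(values, dtype=float)
        return sv.ImportanceEstimate(
            values=values,
            standard_errors=np.full(values.shape, 0.01),
            adjusted=np.zeros(values.shape, dtype=bool),
            model_loss=0.5,
            n_permutations=10,
        )

    def test_flagged_variable_takes_absolute_value(self):
        report = sv.VifReport(vif=np.array([3.0, 1.2]), threshold=2.0)
        out = sv.vif_adjust(self._estimate([-0.05, -0.02]), report)
        assert out.values[0] == pytest.approx(0.05)
        assert out.values[1] == pytest.approx(-0.02)
        assert out.adjusted[0] and not out.adjusted[1]

    def test_threshold_boundary_is_strict(self):
        report = sv.VifReport(vif=np.array([2.0, 2.0 + 1e-9]), threshold=2.0)
        out = sv.vif_adjust(self._estimate([-0.05, -0.05]), report)
        assert out.values[0] == pytest.approx(-0.05)
        assert out.values[1] == pytest.approx(0.05)

    def test_zero_is_a_fixed_point(self):
        report = sv.VifReport(vif=np.array([10.0, 10.0]), threshold=2.0)
        out = sv.vif_adjust(self._estimate([0.0, 0.0]), report)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_standard_errors_pass_through(self):
        report = sv.VifReport(vif=np.array([3.0, 1.0]), threshold=2.0)
        est = self._estimate([-0.05, 0.02])
        out = sv.vif_adjust(est, report)
        np.testing.assert_array_equal(out.standard_errors, est.standard_errors)


class TestComputeCloud:
    @pytest.fixture(scope="class")
    def setup(self, request):
        spec = sv.SyntheticSpec(
            n=300, d=3, coefficients=np.array([0.0, 0.8, -0.5, 0.0]),
            correlation=np.eye(3), seed=21,
        )
        data = sv.generate(spec, test_fraction=0.3)
        optimal = sv.fit_optimal_model(data)
        vif = sv.compute_vif(data)
        return data, optimal, vif

    def test_singleton_cloud_matches_direct_estimate(self, setup):
        data, optimal, vif = setup
        ens = sv.RashomonEnsemble(
            coefficients=optimal.coefficients[None, :],
            losses=np.array([optimal.train_loss]),
            optimal_loss=optimal.train_loss,
            epsilon=0.05, acceptance_count=0, proposal_count=0,
        )
        cloud = sv.compute_cloud(ens, data, vif, n_permutations=30, seed=5)
        assert cloud.m == 1
        rng = np.random.default_rng(5)
        X_train, _ = data.rows("train")
        ref = X_train[rng.choice(X_train.shape[0], size=128, replace=False)]
        direct = sv.sage_estimate(
            optimal.coefficients,
            CoalitionSpec(kind="global_sage", reference=ref,
                          evaluation=data.rows("test")),
            n_permutations=30, seed=6,
        )
        np.testing.assert_allclose(cloud.values[0],
                                   sv.vif_adjust(direct, vif).values)

    def test_bookkeeping_and_determinism(self, setup):
        data, optimal, vif = setup
        ens = sv.sample_rashomon(
            optimal, data,
            sv.SamplerConfig(m0=100, final_size=10, u1=5, u2=20, seed=2),
        )
        c1 = sv.compute_cloud(ens, data, vif, n_permutations=20, seed=9)
        c2 = sv.compute_cloud(ens, data, vif, n_permutations=20, seed=9)
        np.testing.assert_array_equal(c1.values, c2.values)
        np.testing.assert_array_equal(c1.standard_errors, c2.standard_errors)
        np.testing.assert_array_equal(c1.losses, ens.losses)
        assert c1.names == data.names

    def test_round_trip_through_long_format(self, setup):
        data, optimal, vif = setup
        ens = sv.sample_rashomon(
            optimal, data,
            sv.SamplerConfig(m0=50, final_size=5, u1=5, u2=20, seed=3),
        )
        cloud = sv.compute_cloud(ens, data, vif, n_permutations=10, seed=1)
        back = sv.ImportanceCloud.from_frame(cloud.to_frame())
        np.testing.assert_allclose(back.values, cloud.values)
        np.testing.assert_allclose(back.standard_errors, cloud.standard_errors)
        assert back.names == cloud.names
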