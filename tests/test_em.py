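import numpy as np
import pytest
from scipy.stats import norm

import trajmoe as tm
from trajmoe.em import (
    _gate_l1,
    bic,
    classify,
    e_step,
    n_free_parameters,
    observed_loglik,
    penalized_objective,
)
from trajmoe.experts import expert_loglik_matrix
from trajmoe.gating import gating_log_probs

from conftest import random_soft_instance


def _random_params(seed, K, V, P, L):
    rng = np.random.default_rng(seed)
    omega = rng.normal(size=(K, L))
    omega[0] = 0
    omega0 = np.concatenate([[0.0], rng.normal(size=K - 1)]) if K > 1 else np.zeros(1)
    return tm.ModelParameters(
        rng.normal(size=(K, V, P + 1)), rng.uniform(0.5, 2.0, (K, V)), omega0, omega
    )


class TestEStep:
    def test_single_class_gives_unit_responsibilities(self):
        clinical, geno, _ = random_soft_instance(0, N=10, K=1, L=3)
        params = _random_params(0, 1, 2, 1, 3)
        tau = e_step(clinical, geno, params)
        np.testing.assert_allclose(tau.tau, 1.0)

    def test_equal_expert_likelihoods_reduce_to_gate(self):
        # identical expert blocks across classes: posterior equals the gate
        clinical, geno, _ = random_soft_instance(1, N=12, K=2, L=3)
        rng = np.random.default_rng(1)
        alpha = np.tile(rng.normal(size=(1, 2, 2)), (2, 1, 1))
        sigma = np.tile(rng.uniform(0.5, 2, (1, 2)), (2, 1))
        omega = rng.normal(size=(2, 3)); omega[0] = 0
        params = tm.ModelParameters(alpha, sigma, np.array([0.0, 0.4]), omega)
        tau = e_step(clinical, geno, params)
        np.testing.assert_allclose(
            tau.tau, np.exp(gating_log_probs(geno.values, params.omega0, params.omega)),
            atol=1e-12,
        )

    def test_hand_computed_two_class_posterior(self):
        # equal gate, expert log-liks (-1, -3): tau = softmax(-1, -3)
        expected = np.exp([-1.0, -3.0]) / np.exp([-1.0, -3.0]).sum()
        assert expected[0] == pytest.approx(0.8808, abs=1e-4)
        # realize it with a single-visit patient engineered to those log-liks
        # log phi(y; mu, 1) = -0.5 log(2 pi) - 0.5 (y-mu)^2 = -1 or -3
        d1 = np.sqrt(2 * (1 - 0.5 * np.log(2 * np.pi)))
        d2 = np.sqrt(2 * (3 - 0.5 * np.log(2 * np.pi)))
        clinical = tm.LongitudinalClinicalData(
            ["p"], [np.array([0.0])], [np.array([[0.0]])], ["v"]
        )
        alpha = np.array([[[d1, 0.0]], [[d2, 0.0]]])
        params = tm.ModelParameters(alpha, np.ones((2, 1)), np.zeros(2), np.zeros((2, 0)))
        tau = e_step(clinical, np.zeros((1, 0)), params)
        np.testing.assert_allclose(tau.tau[0], expected, atol=1e-10)


class TestClassify:
    def test_argmax_and_tie_rule(self):
        tau = tm.Responsibilities(np.array([[0.2, 0.8], [0.5, 0.5]]))
        np.testing.assert_array_equal(classify(tau), [1, 0])

    def test_one_hot_rows_are_a_fixed_point(self, strong_ds):
        cfg = tm.EMConfig(K=2, P=1, mode="cem", n_init=2, seed=0)
        res = tm.fit(strong_ds.clinical, strong_ds.geno, cfg)
        tau2 = e_step(strong_ds.clinical, strong_ds.geno, res.params)
        np.testing.assert_array_equal(classify(tau2), res.labels)


class TestObjectives:
    def test_k1_lambda0_equals_plain_regression_loglik(self):
        clinical, geno, _ = random_soft_instance(2, N=15, K=1, L=2)
        params = _random_params(2, 1, 2, 1, 2)
        tau = tm.Responsibilities(np.ones((15, 1)))
        obj = penalized_objective(clinical, geno, tau, params, 0.0)
        ll = float(expert_loglik_matrix(clinical, params).sum())
        assert obj == pytest.approx(ll, abs=1e-10)

    def test_linear_in_lambda_with_standardized_norm(self):
        clinical, geno, tau = random_soft_instance(3, N=20, K=3, L=4)
        params = _random_params(3, 3, 2, 1, 4)
        o1 = penalized_objective(clinical, geno, tau, params, 0.1)
        o2 = penalized_objective(clinical, geno, tau, params, 0.2)
        drop = 20 * 0.1 * _gate_l1(geno, params.omega)
        assert o1 - o2 == pytest.approx(drop, rel=1e-10)

    def test_matches_naive_term_by_term_summation(self):
        clinical, geno, tau = random_soft_instance(4, N=8, K=2, V=2, L=3)
        params = _random_params(4, 2, 2, 1, 3)
        lam = 0.07
        # independent naive oracle: loop over patients, classes, visits, vars
        eta = np.exp(gating_log_probs(geno.values, params.omega0, params.omega))
        total = 0.0
        for i in range(8):
            for k in range(2):
                cell_sum = np.log(eta[i, k])
                t = clinical.times[i] / params.time_scale
                for j, tj in enumerate(t):
                    for v in range(2):
                        mu = params.alpha[k, v, 0] + params.alpha[k, v, 1] * tj
                        cell_sum += norm.logpdf(clinical.values[i][j, v], mu, params.sigma[k, v])
                total += tau.tau[i, k] * cell_sum
        sd = geno.values.std(axis=0)
        total -= 8 * lam * float((np.abs(params.omega) * sd).sum())
        obj = penalized_objective(clinical, geno, tau, params, lam)
        assert obj == pytest.approx(total, abs=1e-10)

    def test_observed_loglik_naive_oracle_and_jensen_bound(self):
        clinical, geno, tau = random_soft_instance(5, N=8, K=3, V=2, L=3)
        params = _random_params(5, 3, 2, 1, 3)
        eta = np.exp(gating_log_probs(geno.values, params.omega0, params.omega))
        ell = expert_loglik_matrix(clinical, params)
        naive = float(np.log((eta * np.exp(ell)).sum(axis=1)).sum())
        ll = observed_loglik(clinical, geno, params)
        assert ll == pytest.approx(naive, abs=1e-10)
        lam = 0.05
        pen_obj = penalized_objective(clinical, geno, tau, params, lam)
        assert ll >= pen_obj + 8 * lam * _gate_l1(geno, params.omega) - 1e-10

    def test_k1_observed_equals_expert_total(self):
        clinical, geno, _ = random_soft_instance(6, N=10, K=1, L=2)
        params = _random_params(6, 1, 2, 1, 2)
        assert observed_loglik(clinical, geno, params) == pytest.approx(
            float(expert_loglik_matrix(clinical, params).sum()), abs=1e-10
        )


class TestBIC:
    def test_minimal_model_counts_mean_and_sd(self):
        params = tm.ModelParameters(np.zeros((1, 1, 1)), np.ones((1, 1)),
                                    np.zeros(1), np.zeros((1, 5)))
        assert n_free_parameters(params) == 2

    def test_stated_counting_rule_arithmetic(self):
        # K=2, V=4, P=1, 10 nonzero omega: 16 + 8 + 1 + 10 = 35
        omega = np.zeros((2, 40))
        omega[1, :10] = 1.0
        params = tm.ModelParameters(np.zeros((2, 4, 2)), np.ones((2, 4)),
                                    np.zeros(2), omega)
        assert n_free_parameters(params) == 35

    def test_zero_coefficient_marker_leaves_bic_unchanged(self):
        clinical, geno, _ = random_soft_instance(7, N=10, K=2, L=3)
        params = _random_params(7, 2, 2, 1, 3)
        ll = observed_loglik(clinical, geno, params)
        b1 = bic((ll, params), clinical)
        # append an inactive marker column
        omega2 = np.column_stack([params.omega, np.zeros(2)])
        params2 = tm.ModelParameters(params.alpha, params.sigma, params.omega0, omega2)
        assert bic((ll, params2), clinical) == b1


class TestFit:
    def test_well_separated_toy_recovers_truth_every_seed(self, strong_ds):
        for seed in range(10):
            cfg = tm.EMConfig(K=2, P=1, mode="cem", n_init=2, seed=seed)
            res = tm.fit(strong_ds.clinical, strong_ds.geno, cfg)
            assert tm.adjusted_rand_index(strong_ds.true_labels, res.labels) == 1.0

    def test_k1_equals_single_weighted_regression(self):
        clinical, geno, _ = random_soft_instance(8, N=20, K=1, L=2)
        cfg = tm.EMConfig(K=1, P=1, n_init=1, seed=0, time_scale=1.0)
        res = tm.fit(clinical, geno, cfg)
        from trajmoe.experts import update_expert_params

        tau1 = tm.Responsibilities(np.ones((20, 1)))
        alpha, sigma = update_expert_params(clinical, tau1, 1, time_scale=1.0)
        np.testing.assert_allclose(res.params.alpha, alpha, atol=1e-10)
        np.testing.assert_allclose(res.params.sigma, sigma, atol=1e-10)

    def test_different_seeds_agree_up_to_relabeling(self, strong_ds):
        cfg1 = tm.EMConfig(K=2, P=1, n_init=2, seed=1)
        cfg2 = tm.EMConfig(K=2, P=1, n_init=2, seed=99)
        r1 = tm.fit(strong_ds.clinical, strong_ds.geno, cfg1)
        r2 = tm.fit(strong_ds.clinical, strong_ds.geno, cfg2)
        assert tm.adjusted_rand_index(r1.labels, r2.labels) == 1.0
        assert r1.bic == pytest.approx(r2.bic, rel=1e-6)

    def test_needs_more_patients_than_clusters(self):
        clinical, geno, _ = random_soft_instance(9, N=3, K=2, L=2)
        with pytest.raises(ValueError):
            tm.fit(clinical, geno, tm.EMConfig(K=3, n_init=1))


class TestTwoStep:
    def test_constant_gate_weights_normalize(self, toy_ds):
        cfg = tm.EMConfig(K=2, P=1, n_init=2, seed=0)
        res = tm.fit(toy_ds.clinical, toy_ds.geno, tm.EMConfig(K=2, P=1, n_init=2,
                                                               seed=0, gate="constant",
                                                               debias=False))
        # stage-1 gate is intercept-only: no marker enters the weights
        assert np.count_nonzero(res.params.omega) == 0
        pi = np.exp(res.params.omega0) / np.exp(res.params.omega0).sum()
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_trajectory_driven_clusters_match_integrative(self, strong_ds):
        cfg = tm.EMConfig(K=2, P=1, n_init=3, seed=0)
        integ = tm.fit(strong_ds.clinical, strong_ds.geno, cfg)
        two = tm.fit_two_step(strong_ds.clinical, strong_ds.geno, cfg)
        assert tm.adjusted_rand_index(integ.labels, two.labels) == 1.0

    def test_two_step_reports_selection_support(self, strong_ds):
        cfg = tm.EMConfig(K=2, P=1, n_init=2, seed=0)
        res = tm.fit_two_step(strong_ds.clinical, strong_ds.geno, cfg)
        assert res.support == {(int(k), int(l)) for k, l in zip(*np.nonzero(res.params.omega))}
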