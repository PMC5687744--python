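"""Pseudo-regression, adaptive weights, Gram-form LARS path and eBIC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minssm.erm import ERMConfig
from minssm.kalman import kalman_filter, kalman_smoother, plugin_statistics
from minssm.regularization import (
    LassoPath,
    MatrixVariantCapacityError,
    adaptive_weights,
    build_pseudo_regression,
    ebic_select,
    lars_path_gram,
    marginal_A,
    mle_A,
    rstep_matrix,
    rstep_row,
)
from minssm.ssm import SSMParameters, simulate_ssm
from conftest import random_stable_params
from oracles import (
    adaptive_lasso_enumerate,
    adaptive_lasso_kkt_ok,
    conditional_state_moments,
)


def _noiseless_states(rng, p, T, n_nonzero=None, A=None):
    """States following x_t = A x_{t-1} exactly, plus plug-in statistics."""
    if A is None:
        A = rng.standard_normal((p, p))
        A *= 0.7 / np.abs(np.linalg.eigvals(A)).max()
    X = np.empty((T, p))
    X[0] = rng.standard_normal(p)
    for t in range(1, T):
        X[t] = A @ X[t - 1] + 1e-8 * rng.standard_normal(p)  # generic states
    return A, plugin_statistics(X)


class TestPseudoRegression:
    def test_plugin_gram_is_exact_sum_of_outer_products(self, rng):
        X = rng.standard_normal((7, 3))
        pr = build_pseudo_regression(plugin_statistics(X))
        assert np.allclose(pr.G, sum(np.outer(x, x) for x in X[:-1]))
        assert pr.n_eff == 6

    def test_scalar_case_reduces_to_sums(self, rng):
        x = rng.standard_normal(5)
        pr = build_pseudo_regression(plugin_statistics(x[:, None]))
        assert pr.G[0, 0] == pytest.approx(np.sum(x[:-1] ** 2))
        assert pr.c[0, 0] == pytest.approx(np.sum(x[1:] * x[:-1]))
        assert pr.yy[0] == pytest.approx(np.sum(x[1:] ** 2))

    def test_quadratic_form_equals_monte_carlo_expected_rss(self, rng):
        """yy_i - 2a'c_i + a'Ga must equal E||X_i - Z*a||^2 over the smoothing law."""
        params = random_stable_params(rng, p=2)
        _, Y = simulate_ssm(params, T=4, seed=3)
        ss = kalman_smoother(params, kalman_filter(params, Y))
        pr = build_pseudo_regression(ss)
        post_mean, post_cov = conditional_state_moments(params, Y.Y)
        L = np.linalg.cholesky(post_cov + 1e-12 * np.eye(post_cov.shape[0]))
        a = rng.standard_normal(2)
        i = 0
        n_mc = 200_000
        draws = post_mean.reshape(-1) + (
            L @ rng.standard_normal((post_cov.shape[0], n_mc))
        ).T
        draws = draws.reshape(n_mc, 4, 2)
        resid = draws[:, 1:, i] - draws[:, :-1, :] @ a
        mc = np.mean(np.sum(resid**2, axis=1))
        exact = pr.yy[i] - 2 * a @ pr.c[i] + a @ pr.G @ a
        assert exact == pytest.approx(mc, rel=0.02)


class TestReferenceEstimators:
    def test_mle_recovers_A_from_noiseless_states(self, rng):
        A, ss = _noiseless_states(rng, p=3, T=30)
        assert np.allclose(mle_A(ss), A, atol=1e-5)

    def test_scalar_mle_is_ratio_of_sums(self, rng):
        x = rng.standard_normal(8)
        ss = plugin_statistics(x[:, None])
        expected = np.sum(x[1:] * x[:-1]) / np.sum(x[:-1] ** 2)
        assert mle_A(ss)[0, 0] == pytest.approx(expected, abs=1e-12)
        assert marginal_A(ss)[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_mle_matches_normal_equation_oracle(self, rng):
        params = random_stable_params(rng, p=2)
        _, Y = simulate_ssm(params, T=10, seed=21)
        ss = kalman_smoother(params, kalman_filter(params, Y))
        A_hat = mle_A(ss)
        # normal equations of the lambda=0 objective: A G = C (rowwise)
        assert np.allclose(A_hat @ ss.S11, ss.S10, atol=1e-8)

    def test_marginal_equals_mle_for_diagonal_S11(self, rng):
        _, ss = _noiseless_states(rng, p=3, T=20)
        ss.S11 = np.diag(np.diag(ss.S11))
        assert np.allclose(marginal_A(ss), mle_A(ss), atol=1e-10)

    def test_marginal_entrywise(self, rng):
        params = random_stable_params(rng, p=3)
        _, Y = simulate_ssm(params, T=8, seed=2)
        ss = kalman_smoother(params, kalman_filter(params, Y))
        M = marginal_A(ss)
        for i in range(3):
            for j in range(3):
                assert M[i, j] == pytest.approx(ss.S10[i, j] / ss.S11[j, j])


class TestAdaptiveWeights:
    def test_reciprocal_magnitude(self):
        W = adaptive_weights(np.array([[0.5, -0.4], [0.0, 2.0]])).W
        assert W[0, 0] == pytest.approx(2.0)
        assert W[0, 1] == pytest.approx(2.5)
        assert np.isinf(W[1, 0])
        assert W[1, 1] == pytest.approx(0.5)

    def test_sign_has_no_effect(self):
        assert adaptive_weights(np.array([[-0.4]])).W[0, 0] == pytest.approx(
            adaptive_weights(np.array([[0.4]])).W[0, 0]
        )


class TestLarsPathGram:
    def test_orthonormal_design_soft_thresholding(self, rng):
        n, p = 50, 4
        G = n * np.eye(p)
        c = np.array([30.0, -12.0, 4.0, 0.5])
        path = lars_path_gram(G, c, yy_i=100.0, w_i=np.ones(p), n_eff=n)
        for lam in (10.0, 25.0, 40.0):
            expected = np.sign(c / n) * np.maximum(np.abs(c / n) - lam / (2 * n), 0.0)
            assert np.allclose(path.coefs_at(lam), expected, atol=1e-8)

    def test_first_breakpoint_is_null_model(self, rng):
        params = random_stable_params(rng, p=3)
        _, Y = simulate_ssm(params, T=12, seed=4)
        ss = kalman_smoother(params, kalman_filter(params, Y))
        pr = build_pseudo_regression(ss)
        path = lars_path_gram(pr.G, pr.c[0], pr.yy[0], np.ones(3), pr.n_eff)
        assert np.count_nonzero(path.coefs[0]) == 0
        assert np.allclose(path.coefs_at(path.breakpoints[0] * 2), 0.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((12, 3))
        G = Z.T @ Z
        c = Z.T @ rng.standard_normal(12)
        yy = 50.0
        w = rng.uniform(0.5, 3.0, size=3)
        path = lars_path_gram(G, c, yy, w, n_eff=12)
        lams = path.breakpoints
        probes = np.unique(
            np.concatenate([0.5 * (lams[:-1] + lams[1:]), lams[1:-1]])
        )[:5]
        for lam in probes:
            if lam <= 0:
                continue
            a = path.coefs_at(lam)
            oracle = adaptive_lasso_enumerate(G, c, w, lam)
            assert np.allclose(a, oracle, atol=1e-6)
            assert adaptive_lasso_kkt_ok(G, c, w, lam, a, tol=1e-6)

    def test_infinite_weights_frozen_out(self, rng):
        Z = rng.standard_normal((15, 4))
        G, c = Z.T @ Z, Z.T @ rng.standard_normal(15)
        w = np.array([1.0, np.inf, 1.0, np.inf])
        path = lars_path_gram(G, c, 40.0, w, n_eff=15)
        assert np.allclose(path.coefs[:, [1, 3]], 0.0)

    def test_all_weights_infinite_gives_null_path(self):
        path = lars_path_gram(np.eye(2), np.ones(2), 5.0, np.full(2, np.inf), 10)
        assert np.allclose(path.coefs, 0.0)
        assert path.rss[0] == pytest.approx(5.0)

    def test_weighted_l1_norm_nondecreasing_along_path(self, rng):
        Z = rng.standard_normal((25, 5))
        G, c = Z.T @ Z, Z.T @ rng.standard_normal(25)
        w = rng.uniform(0.5, 2.0, size=5)
        path = lars_path_gram(G, c, 60.0, w, n_eff=25)
        norms = np.sum(np.abs(path.coefs) * w[None, :], axis=1)
        assert np.all(np.diff(norms) >= -1e-10)


class TestEBIC:
    def _path(self, rss, ks, p=5):
        coefs = np.zeros((len(rss), p))
        for i, k in enumerate(ks):
            coefs[i, :k] = 1.0
        return LassoPath(
            breakpoints=np.linspace(10, 1, len(rss)),
            coefs=coefs,
            rss=np.asarray(rss, dtype=float),
        )

    def test_gamma_zero_is_plain_bic(self):
        path = self._path([10.0, 6.0, 5.9], [0, 1, 2])
        sel = ebic_select(path, n_eff=50, p_total=20, gamma=0.0)
        n = 50
        bic = n * np.log(np.array([10, 6, 5.9]) / n) + np.array([0, 1, 2]) * np.log(n)
        assert sel.chosen_index == int(np.argmin(bic))

    def test_equal_rss_prefers_smaller_model(self):
        path = self._path([4.0, 4.0], [2, 3])
        sel = ebic_select(path, n_eff=50, p_total=20, gamma=1.0)
        assert sel.chosen_index == 0

    def test_hand_computed_scores(self):
        from math import comb, log

        rss = [20.0, 12.0, 9.0, 8.5]
        ks = [0, 1, 2, 3]
        path = self._path(rss, ks, p=4)
        n, P, g = 50, 20, 1.0
        scores = [
            n * log(r / n) + k * log(n) + 2 * g * log(comb(P, k))
            for r, k in zip(rss, ks)
        ]
        sel = ebic_select(path, n_eff=n, p_total=P, gamma=g)
        assert np.allclose(sel.scores, scores, atol=1e-10)
        assert sel.chosen_index == int(np.argmin(scores))


class TestRSteps:
    def _cfg(self, **kw):
        return ERMConfig(**kw)

    def test_null_system_mostly_empty_support(self, rng):
        hits = 0
        for s in range(6):
            p = 4
            params = SSMParameters(
                A=np.zeros((p, p)), sigma_Q=1.0, sigma_R=0.1,
                mu=np.zeros(p), Sigma=np.eye(p),
            )
            _, Y = simulate_ssm(params, T=40, seed=100 + s)
            ss = kalman_smoother(params, kalman_filter(params, Y))
            A_hat = rstep_row(ss, self._cfg())
            hits += np.count_nonzero(A_hat)
        # 6 replicates x 16 candidate entries: expect near-zero selections
        assert hits <= 6

    def test_observed_states_sparse_system_exact_recovery(self):
        """System-excited states observed without measurement error: the
        plug-in R step must recover the generating support exactly."""
        p, T = 5, 40
        A = np.zeros((p, p))
        pos = [(0, 1), (1, 3), (2, 2), (3, 0), (4, 1), (4, 4)]
        vals = [0.6, -0.5, 0.7, 0.4, -0.8, 0.5]
        for (i, j), v in zip(pos, vals):
            A[i, j] = v
        params = SSMParameters(A=A, sigma_Q=1e-8, sigma_R=0.0,
                               mu=np.zeros(p), Sigma=np.eye(p))
        X, _ = simulate_ssm(params, T, seed=31)
        ss = plugin_statistics(X.X)
        for variant in (rstep_row, rstep_matrix):
            A_hat = variant(ss, self._cfg())
            assert np.array_equal(A_hat != 0, A != 0), variant.__name__

    def test_row_and_matrix_agree_at_p1(self, rng):
        params = random_stable_params(rng, p=1)
        _, Y = simulate_ssm(params, T=20, seed=5)
        ss = kalman_smoother(params, kalman_filter(params, Y))
        assert np.allclose(rstep_row(ss, self._cfg()), rstep_matrix(ss, self._cfg()))

    def test_matrix_variant_capacity_guard(self, rng):
        p = 7
        params = random_stable_params(rng, p=p)
        _, Y = simulate_ssm(params, T=15, seed=6)
        ss = kalman_smoother(params, kalman_filter(params, Y))
        with pytest.raises(MatrixVariantCapacityError, match="row-based"):
            rstep_matrix(ss, self._cfg(matrix_p_max=5))

    def test_selected_support_never_exceeds_mle_support(self, rng):
        params = random_stable_params(rng, p=4)
        _, Y = simulate_ssm(params, T=30, seed=7)
        ss = kalman_smoother(params, kalman_filter(params, Y))
        A_hat = rstep_row(ss, self._cfg())
        assert np.count_nonzero(A_hat) <= np.count_nonzero(mle_A(ss))
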