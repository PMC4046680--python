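"""Unit and property tests for the categorical PCA core."""

import numpy as np
import pytest

from scpca.cpca import (
    CPCAModel,
    FitConfig,
    encode_one_hot,
    first_pc_scores,
    fit_cpca,
    log_likelihood,
    newton_step_loadings,
    newton_step_offsets,
    newton_step_scores,
    orthonormalize,
)
from tests.conftest import sample_categorical


class TestEncodeOneHot:
    def test_indicator_definition(self):
        X = encode_one_hot(np.array([[0, 2], [1, 1]]))
        ind = X.indicators
        assert np.array_equal(ind[0], [[1, 0], [0, 0]])
        assert np.array_equal(ind[1], [[0, 0], [1, 1]])
        assert np.array_equal(ind[2], [[0, 1], [0, 0]])

    def test_partition_of_unity(self, rng):
        X = encode_one_hot(rng.integers(0, 3, (7, 5)))
        assert np.array_equal(X.indicators.sum(axis=0), np.ones((7, 5)))

    def test_single_cell(self):
        X = encode_one_hot(np.array([[2]]))
        assert X.indicators[2][0, 0] == 1 and X.indicators.sum() == 1

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            encode_one_hot(np.array([[3]]))


class TestLogLikelihood:
    def test_uniform_parameters_give_log_third_per_cell(self):
        X = encode_one_hot(np.array([[0, 2], [1, 1]]))
        ll = log_likelihood(
            X, U=np.zeros((2, 1)), V=np.zeros((2, 2, 1)), mu=np.zeros((2, 2))
        )
        assert ll == pytest.approx(-4 * np.log(3), abs=1e-12)

    def test_single_cell_closed_form(self):
        # observed category 1 with theta1 = 1, theta2 = -1
        X = encode_one_hot(np.array([[1]]))
        ll = log_likelihood(
            X, U=np.zeros((1, 1)), V=np.zeros((2, 1, 1)),
            mu=np.array([[1.0], [-1.0]]),
        )
        expected = 1.0 - np.log(1 + np.e + np.exp(-1.0))
        assert ll == pytest.approx(expected, abs=1e-12)
        assert ll == pytest.approx(-0.407606, abs=1e-5)

    def test_saturated_cell_contribution_vanishes(self):
        X = encode_one_hot(np.array([[1]]))
        ll = log_likelihood(
            X, U=np.zeros((1, 1)), V=np.zeros((2, 1, 1)),
            mu=np.array([[200.0], [0.0]]),
        )
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_always_nonpositive(self, rng):
        X = encode_one_hot(rng.integers(0, 3, (6, 4)))
        for _ in range(5):
            ll = log_likelihood(
                X,
                U=rng.standard_normal((6, 2)),
                V=rng.standard_normal((2, 4, 2)),
                mu=rng.standard_normal((2, 4)),
            )
            assert ll <= 0


class TestNewtonSteps:
    def test_hand_derived_score_update(self):
        # n=1, d=1, l=1, V1=1, V2=0, mu=0, observed category 1, u=0:
        # gradient 2/3, Hessian -2/9, undamped Newton update u = 3
        X = encode_one_hot(np.array([[1]]))
        U = np.zeros((1, 1))
        V = np.array([[[1.0]], [[0.0]]])
        mu = np.zeros((2, 1))
        U1 = newton_step_scores(X, U, V, mu, damping=0)
        assert U1[0, 0] == pytest.approx(3.0, abs=1e-10)

    def test_hand_derived_loading_update_by_symmetry(self):
        # roles of u and V exchanged: U fixed at 1, V starts at 0
        X = encode_one_hot(np.array([[1]]))
        U = np.ones((1, 1))
        V = np.zeros((2, 1, 1))
        mu = np.zeros((2, 1))
        V1 = newton_step_loadings(X, U, V, mu, damping=0)
        assert V1[0, 0, 0] == pytest.approx(3.0, abs=1e-10)

    def test_stationary_row_unchanged(self):
        # counts (10,10,10) with U=0: offsets 0 are already the MLE and the
        # score gradient vanishes, so nothing moves
        codes = np.array([[0]] * 10 + [[1]] * 10 + [[2]] * 10)
        X = encode_one_hot(codes)
        U = np.zeros((30, 1))
        V = np.zeros((2, 1, 1))
        mu = np.zeros((2, 1))
        assert np.array_equal(newton_step_scores(X, U, V, mu), U)
        assert np.array_equal(newton_step_offsets(X, U, V, mu), mu)

    def test_offsets_converge_to_multinomial_logit_mle(self):
        # U = 0: closed form mu_k = log(n_k / n_0)
        codes = np.array([[0]] * 2 + [[1]] * 5 + [[2]] * 3)
        X = encode_one_hot(codes)
        mu = np.zeros((2, 1))
        U, V = np.zeros((10, 1)), np.zeros((2, 1, 1))
        for _ in range(50):
            mu = newton_step_offsets(X, U, V, mu)
        assert mu[0, 0] == pytest.approx(np.log(5 / 2), abs=1e-6)
        assert mu[1, 0] == pytest.approx(np.log(3 / 2), abs=1e-6)

    def test_gradients_match_finite_differences(self, rng):
        codes, _ = sample_categorical(rng, 5, 3)
        X = encode_one_hot(codes)
        U = 0.3 * rng.standard_normal((5, 2))
        V = 0.3 * rng.standard_normal((2, 3, 2))
        mu = 0.3 * rng.standard_normal((2, 3))
        from scpca.cpca import _probs, _theta

        p = _probs(_theta(U, V, mu))
        resid = np.stack([(X.codes == k + 1) - p[k] for k in range(2)])
        gU = np.einsum("knj,kjl->nl", resid, V)
        gV = np.stack([resid[k].T @ U for k in range(2)])
        gmu = resid.sum(axis=1)
        eps = 1e-6

        def ll(U_, V_, mu_):
            return log_likelihood(X, U=U_, V=V_, mu=mu_)

        base_args = (U, V, mu)
        for arr, grad in ((U, gU), (V, gV), (mu, gmu)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                pert = arr.copy()
                pert[idx] += eps
                args = [pert if a is arr else a for a in base_args]
                num = (ll(*args) - ll(*base_args)) / eps
                assert num == pytest.approx(grad[idx], abs=1e-5)

    def test_damped_steps_never_decrease_likelihood(self, rng):
        for _ in range(10):
            codes, _ = sample_categorical(rng, 8, 4)
            X = encode_one_hot(codes)
            U = 0.5 * rng.standard_normal((8, 1))
            V = 0.5 * rng.standard_normal((2, 4, 1))
            mu = 0.5 * rng.standard_normal((2, 4))
            before = log_likelihood(X, U=U, V=V, mu=mu)
            U2 = newton_step_scores(X, U, V, mu)
            assert log_likelihood(X, U=U2, V=V, mu=mu) >= before - 1e-9
            V2 = newton_step_loadings(X, U2, V, mu)
            mid = log_likelihood(X, U=U2, V=V2, mu=mu)
            assert mid >= log_likelihood(X, U=U2, V=V, mu=mu) - 1e-9
            mu2 = newton_step_offsets(X, U2, V2, mu)
            assert log_likelihood(X, U=U2, V=V2, mu=mu2) >= mid - 1e-9


class TestOrthonormalize:
    def test_theta_invariance_and_orthonormality(self, rng):
        U = rng.standard_normal((6, 2))
        V = rng.standard_normal((2, 4, 2))
        mu = rng.standard_normal((2, 4))
        from scpca.cpca import _theta

        th_before = _theta(U, V, mu)
        U2, V2 = orthonormalize(U, V)
        th_after = _theta(U2, V2, mu)
        assert np.abs(th_before - th_after).max() < 1e-10
        stacked = V2.reshape(-1, 2)
        assert np.abs(stacked.T @ stacked - np.eye(2)).max() < 1e-12

    def test_orthonormal_input_unchanged_up_to_sign(self):
        q = np.zeros((2, 3, 1))
        q[0, 0, 0] = 1.0
        U = np.ones((4, 1))
        U2, V2 = orthonormalize(U, q)
        assert np.abs(np.abs(V2) - np.abs(q)).max() < 1e-12

    def test_rank_deficient_raises(self):
        V = np.zeros((2, 3, 2))
        V[0, :, 0] = [1.0, 0, 0]
        V[0, :, 1] = [2.0, 0, 0]  # column 2 collinear with column 1
        with pytest.raises(np.linalg.LinAlgError):
            orthonormalize(np.ones((4, 2)), V)


class TestFitCpca:
    def test_trace_monotone_and_final_orthonormal(self, rng):
        codes, _ = sample_categorical(rng, 30, 6)
        m = fit_cpca(codes, FitConfig(latent_dim=1, n_restarts=2, seed=0))
        assert np.all(np.diff(m.ll_trace) >= -1e-8)
        stacked = m.loadings.reshape(-1, 1)
        assert abs(stacked.T @ stacked - 1.0).max() < 1e-8
        assert m.log_likelihood >= m.ll_trace[0]

    def test_kernel_and_reference_paths_agree(self, rng):
        """The compiled kernel's optimum is a fixed point of the reference
        update equations (cross-implementation consistency)."""
        codes, _ = sample_categorical(rng, 40, 8, scale=0.3)
        cfg = FitConfig(latent_dim=1, n_restarts=2, seed=1, max_iterations=400, tolerance=1e-9)
        mk = fit_cpca(codes, cfg)
        refined = fit_cpca(
            codes,
            FitConfig(latent_dim=1, max_iterations=50, tolerance=1e-12),
            use_kernel=False,
            init=(mk.scores, mk.loadings, mk.offsets),
        )
        gain = refined.log_likelihood - mk.log_likelihood
        assert 0 <= gain < 0.05  # only residual drift, no systematic defect

    def test_latent_dim_two_runs_and_is_orthonormal(self, rng):
        codes, _ = sample_categorical(rng, 25, 6)
        m = fit_cpca(codes, FitConfig(latent_dim=2, n_restarts=1, seed=0, max_iterations=50))
        stacked = m.loadings.reshape(-1, 2)
        assert np.abs(stacked.T @ stacked - np.eye(2)).max() < 1e-8
        assert np.all(np.diff(m.ll_trace) >= -1e-8)

    def test_identical_samples_give_constant_scores_and_marginal_probs(self):
        # every sample identical: the first PC carries no between-sample
        # information and fitted probabilities match the (degenerate)
        # category frequencies
        codes = np.tile(np.array([[0, 1, 2, 1]], dtype=np.int8), (12, 1))
        m = fit_cpca(codes, FitConfig(latent_dim=1, n_restarts=2, seed=3, max_iterations=300))
        s = first_pc_scores(m)
        assert np.std(s) < 1e-3 * (1 + np.abs(s).max())
        probs = m.cell_probabilities()
        emp = np.stack([(codes == k).mean(axis=0) for k in range(3)])
        assert np.abs(probs.mean(axis=1) - emp).max() < 1e-3

    def test_first_pc_sign_follows_minor_allele_counts(self, rng):
        codes, _ = sample_categorical(rng, 50, 10)
        m = fit_cpca(codes, FitConfig(latent_dim=1, n_restarts=1, seed=2, max_iterations=100))
        s = first_pc_scores(m)
        counts = codes.sum(axis=1)
        if np.std(s) > 0 and np.std(counts) > 0:
            assert np.corrcoef(s, counts)[0, 1] >= 0

    def test_bernoulli_reduction_likelihood_identity(self, rng):
        """With the extra category's parameters at the -inf limit, the c=3
        likelihood equals the Bernoulli likelihood at the same theta^1."""
        G = (rng.random((12, 5)) < 0.4).astype(np.int8)
        X3 = encode_one_hot(G, n_categories=3)
        X2 = encode_one_hot(G, n_categories=2)
        U = 0.4 * rng.standard_normal((12, 1))
        V1 = 0.4 * rng.standard_normal((1, 5, 1))
        mu1 = 0.4 * rng.standard_normal((1, 5))
        ll2 = log_likelihood(X2, U=U, V=V1, mu=mu1)
        V3 = np.concatenate([V1, np.zeros_like(V1)], axis=0)
        mu3 = np.concatenate([mu1, np.full_like(mu1, -200.0)], axis=0)
        ll3 = log_likelihood(X3, U=U, V=V3, mu=mu3)
        assert ll3 == pytest.approx(ll2, abs=1e-6)

    def test_bernoulli_reduction_fits_agree_on_weak_signal_data(self, rng):
        u = rng.standard_normal(60)
        v = rng.standard_normal(10) * 0.25
        p = 1 / (1 + np.exp(-(np.outer(u, v) + 0.2)))
        G = (rng.random((60, 10)) < p).astype(np.int8)
        cfg = FitConfig(latent_dim=1, n_restarts=4, seed=0, max_iterations=800, tolerance=1e-10)
        m3 = fit_cpca(G, cfg, n_categories=3)
        m2 = fit_cpca(G, cfg, n_categories=2)
        assert m3.log_likelihood == pytest.approx(m2.log_likelihood, rel=5e-3)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            fit_cpca(np.zeros((4, 2), dtype=np.int8), FitConfig(latent_dim=0))
        with pytest.raises(ValueError):
            fit_cpca(np.zeros((4, 2), dtype=np.int8), FitConfig(latent_dim=4))
        with pytest.raises(ValueError):
            FitConfig(tolerance=-1).validate(10, 5)

    def test_json_roundtrip(self, rng):
        codes, _ = sample_categorical(rng, 10, 4)
        m = fit_cpca(codes, FitConfig(latent_dim=1, n_restarts=1, seed=0, max_iterations=30))
        m2 = CPCAModel.from_json(m.to_json())
        assert np.allclose(m.scores, m2.scores)
        assert m2.log_likelihood == pytest.approx(m.log_likelihood)

    def test_first_pc_scores_requires_fit(self):
        m = CPCAModel(
            scores=np.empty((0, 1)), loadings=np.empty((2, 0, 1)),
            offsets=np.empty((2, 0)), log_likelihood=0.0, converged=False,
            n_iterations=0,
        )
        with pytest.raises(ValueError):
            first_pc_scores(m)


class TestParameterRecovery:
    def test_probability_rmse_shrinks_with_sample_size(self):
        """Fitted cell probabilities approach the rank-1 truth as n grows."""
        d = 20
        rmse = {}
        for n in (100, 400):
            errs = []
            for seed in range(4):
                rng = np.random.default_rng(1000 + seed)
                codes, truth = sample_categorical(rng, n, d, scale=0.5)
                m = fit_cpca(
                    codes,
                    FitConfig(latent_dim=1, n_restarts=2, seed=seed, max_iterations=150,
                              tolerance=1e-6),
                )
                errs.append(np.sqrt(np.mean((m.cell_probabilities() - truth) ** 2)))
            rmse[n] = np.mean(errs)
        assert rmse[400] < rmse[100]
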