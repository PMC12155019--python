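"""Student's-t mixture: densities, E/M steps, target distribution, KL loss."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_t, norm

from decembr.mixture import (
    DegenerateClusterError,
    StudentTMixture,
    TMixtureState,
    clustering_loss,
    e_step,
    init_clusters,
    m_step,
    map_assign,
    mixture_log_likelihood,
    t_log_density,
    target_distribution,
)
from decembr.synthetic import ToySpec, gen_tmm_samples, gen_toy_linear

from conftest import naive_e_step, naive_m_step, naive_t_log_density, naive_target


# ---------------------------------------------------------------------------
# t density


class TestTLogDensity:
    def test_mode_at_center(self, rng):
        center = np.array([1.0, -2.0, 0.5])
        scale = np.array([0.5, 2.0, 1.0])
        at_center = t_log_density(center, center, scale, 2.1)
        for _ in range(20):
            delta = rng.normal(scale=0.5, size=3)
            assert at_center >= t_log_density(center + delta, center, scale, 2.1)

    @pytest.mark.parametrize("z", [0.0, 1.0, 2.0])
    def test_gaussian_limit_1d(self, z):
        # nu -> infinity recovers the standard normal
        logf = t_log_density(np.array([z]), np.zeros(1), np.ones(1), 1e6)
        assert np.exp(logf) == pytest.approx(norm.pdf(z), rel=1e-4)

    def test_gaussian_limit_grid(self):
        grid = np.linspace(-3, 3, 25)
        mu, sig = np.array([0.3, -0.2]), np.array([0.8, 1.7])
        for x in grid:
            z = np.array([x, -x / 2])
            t_val = t_log_density(z, mu, sig, 1e6)
            g_val = (
                norm.logpdf(z[0], mu[0], np.sqrt(sig[0]))
                + norm.logpdf(z[1], mu[1], np.sqrt(sig[1]))
            )
            assert t_val == pytest.approx(g_val, abs=1e-4)

    def test_shape_rate_quadrature_oracle(self):
        # f_t(z) = int N(z; mu, Sigma/u) Gamma(u; nu/2, nu/2) du
        mu = np.array([0.0, 0.0])
        sig = np.array([1.0, 4.0])
        nu = 2.1
        z = np.array([1.0, 2.0])

        def integrand(u):
            dens = np.prod(
                [norm.pdf(z[k], mu[k], np.sqrt(sig[k] / u)) for k in range(2)]
            )
            gamma_pdf = (
                (nu / 2) ** (nu / 2)
                / math.gamma(nu / 2)
                * u ** (nu / 2 - 1)
                * np.exp(-nu / 2 * u)
            )
            return dens * gamma_pdf

        oracle, _ = quad(integrand, 0, np.inf)
        assert np.exp(t_log_density(z, mu, sig, nu)) == pytest.approx(
            oracle, rel=1e-6
        )

    def test_matches_scipy_multivariate_t(self, rng):
        mu = rng.normal(size=4)
        sig = rng.uniform(0.5, 2.0, size=4)
        z = rng.normal(size=4)
        ours = t_log_density(z, mu, sig, 2.1)
        ref = multivariate_t(loc=mu, shape=np.diag(sig), df=2.1).logpdf(z)
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_loop_oracle(self, rng):
        for _ in range(10):
            k = rng.integers(1, 4)
            z, mu = rng.normal(size=(2, k))
            sig = rng.uniform(0.1, 3.0, size=k)
            nu = rng.uniform(2.05, 50)
            assert t_log_density(z, mu, sig, nu) == pytest.approx(
                naive_t_log_density(z, mu, sig, nu), abs=1e-10
            )

    def test_invalid_scale_raises(self):
        with pytest.raises(ValueError, match="positive"):
            t_log_density(np.zeros(2), np.zeros(2), np.array([1.0, 0.0]), 2.1)


# ---------------------------------------------------------------------------
# E-step


class TestEStep:
    def test_identical_components_give_uniform_q(self, rng):
        J, K = 4, 3
        state = TMixtureState(
            centers=np.tile([1.0, 2.0, 3.0], (J, 1)),
            scale_diags=np.tile([0.5, 0.5, 0.5], (J, 1)),
            dof=2.1,
        )
        Q, _ = e_step(rng.normal(size=(20, K)), state)
        assert np.allclose(Q, 1.0 / J, atol=1e-12)

    def test_latent_scale_at_center(self):
        K, nu = 30, 2.1
        state = TMixtureState(
            centers=np.ones((1, K)), scale_diags=np.ones((1, K)), dof=nu
        )
        _, U = e_step(np.ones((1, K)), state)
        assert U[0, 0] == pytest.approx((nu + K) / nu)  # 32.1 / 2.1
        assert U[0, 0] == pytest.approx(15.2857, abs=1e-4)

    def test_far_separated_dominance(self):
        # centers 100 max-scale units apart in each of 3 dimensions
        state = TMixtureState(
            centers=np.array([[0.0, 0.0, 0.0], [100.0, 100.0, 100.0]]),
            scale_diags=np.full((2, 3), 1.0),
            dof=2.1,
        )
        Q, _ = e_step(np.zeros((1, 3)), state)
        assert Q[0, 0] > 1 - 1e-6

    def test_rows_sum_to_one(self, rng, two_component_state):
        Q, U = e_step(rng.normal(size=(50, 3)), two_component_state)
        assert np.allclose(Q.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(U > 0)

    def test_loop_oracle_small_instances(self, rng):
        for _ in range(5):
            n, k, j = rng.integers(2, 11), rng.integers(1, 4), rng.integers(1, 4)
            Z = rng.normal(size=(n, k))
            state = TMixtureState(
                centers=rng.normal(size=(j, k)),
                scale_diags=rng.uniform(0.2, 2.0, size=(j, k)),
                dof=2.1,
            )
            Q, U = e_step(Z, state)
            Q0, U0 = naive_e_step(Z, state)
            np.testing.assert_allclose(Q, Q0, atol=1e-10)
            np.testing.assert_allclose(U, U0, atol=1e-10)

    def test_dimension_mismatch(self, two_component_state):
        with pytest.raises(ValueError, match="features"):
            e_step(np.zeros((5, 2)), two_component_state)


# ---------------------------------------------------------------------------
# M-step


class TestMStep:
    def test_one_hot_unit_u_reduces_to_means_and_variances(self, rng):
        Z = rng.normal(size=(20, 2))
        labels = np.array([0] * 12 + [1] * 8)
        Q = np.eye(2)[labels]
        U = np.ones_like(Q)
        state = TMixtureState(
            centers=np.zeros((2, 2)), scale_diags=np.ones((2, 2)), dof=2.1,
            clamp_floor=1e-12,
        )
        new = m_step(Z, Q, U, state)
        for j in range(2):
            members = Z[labels == j]
            np.testing.assert_allclose(new.centers[j], members.mean(axis=0))
            np.testing.assert_allclose(new.scale_diags[j], members.var(axis=0))

    def test_hand_summed_oracle(self):
        Z = np.array([[0.0], [1.0], [2.0]])
        Q = np.array([[0.9, 0.1], [0.5, 0.5], [0.1, 0.9]])
        U = np.ones_like(Q)
        state = TMixtureState(
            centers=np.zeros((2, 1)), scale_diags=np.ones((2, 1)), dof=2.1,
            clamp_floor=1e-12,
        )
        new = m_step(Z, Q, U, state)
        mu0 = (0.9 * 0 + 0.5 * 1 + 0.1 * 2) / (0.9 + 0.5 + 0.1)
        mu1 = (0.1 * 0 + 0.5 * 1 + 0.9 * 2) / (0.1 + 0.5 + 0.9)
        assert new.centers[0, 0] == pytest.approx(mu0, abs=1e-12)
        assert new.centers[1, 0] == pytest.approx(mu1, abs=1e-12)

    def test_loop_oracle_small_instances(self, rng):
        for _ in range(5):
            n, k, j = rng.integers(3, 11), rng.integers(1, 4), rng.integers(1, 4)
            Z = rng.normal(size=(n, k))
            state = TMixtureState(
                centers=rng.normal(size=(j, k)),
                scale_diags=rng.uniform(0.2, 2.0, size=(j, k)),
                dof=2.1,
                clamp_floor=1e-300,
            )
            Q, U = e_step(Z, state)
            new = m_step(Z, Q, U, state)
            c0, s0 = naive_m_step(Z, Q, U, state)
            np.testing.assert_allclose(new.centers, c0, atol=1e-10)
            np.testing.assert_allclose(new.scale_diags, s0, atol=1e-10)

    def test_clamp_floor_applied(self):
        Z = np.zeros((5, 1))  # zero variance -> scale update hits the floor
        Q = np.ones((5, 1))
        U = np.ones((5, 1))
        state = TMixtureState(
            centers=np.zeros((1, 1)), scale_diags=np.ones((1, 1)), dof=2.1,
            clamp_floor=1e-6,
        )
        new = m_step(Z, Q, U, state)
        assert new.scale_diags[0, 0] == 1e-6

    def test_degenerate_cluster_error_names_index(self):
        Z = np.zeros((3, 1))
        Q = np.array([[1.0, 0.0]] * 3)
        U = np.ones_like(Q)
        state = TMixtureState(
            centers=np.zeros((2, 1)), scale_diags=np.ones((2, 1)), dof=2.1
        )
        with pytest.raises(DegenerateClusterError, match="cluster 1"):
            m_step(Z, Q, U, state)


# ---------------------------------------------------------------------------
# target distribution and KL loss


class TestTargetDistribution:
    def test_uniform_fixed_point(self):
        Q = np.full((10, 4), 0.25)
        P, f = target_distribution(Q)
        assert np.allclose(P, 0.25, atol=1e-12)
        np.testing.assert_allclose(f, Q.sum(axis=0))

    def test_one_hot_fixed_point(self, rng):
        labels = rng.integers(0, 3, size=12)
        Q = np.eye(3)[labels]
        P, _ = target_distribution(Q)
        np.testing.assert_allclose(P, Q)

    def test_sharpening_oracle(self):
        Q = np.array([[0.8, 0.2], [0.6, 0.4]])
        P, f = target_distribution(Q)
        np.testing.assert_allclose(P, naive_target(Q), atol=1e-12)
        assert P[0, 0] > Q[0, 0]  # confidence sharpened
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_cluster_error(self):
        Q = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DegenerateClusterError):
            target_distribution(Q)


class TestClusteringLoss:
    def test_kl_identity(self, rng):
        Q = rng.dirichlet(np.ones(3), size=10)
        assert clustering_loss(Q, Q) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_collapse_gives_exact_zero(self, rng):
        # identical centers and scales: Q uniform, P uniform, loss exactly 0
        J = 3
        state = TMixtureState(
            centers=np.zeros((J, 2)), scale_diags=np.ones((J, 2)), dof=2.1
        )
        Q, _ = e_step(rng.normal(size=(30, 2)), state)
        P, _ = target_distribution(Q)
        assert clustering_loss(Q, P) == 0.0

    def test_two_term_oracle_positive(self):
        Q = np.array([[0.8, 0.2]])
        P = np.array([[0.9, 0.1]])
        expected = 0.9 * np.log(0.9 / 0.8) + 0.1 * np.log(0.1 / 0.2)
        got = clustering_loss(Q, P)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 0  # Gibbs' inequality

    def test_infinite_loss_sentinel(self):
        Q = np.array([[1.0, 0.0]])
        P = np.array([[0.5, 0.5]])
        with pytest.warns(RuntimeWarning, match="infinite"):
            assert clustering_loss(Q, P) == np.inf


# ---------------------------------------------------------------------------
# initialization, likelihood, MAP


class TestInitClusters:
    def test_two_point_masses(self):
        Z = np.array([[0.0]] * 10 + [[1.0]] * 10)
        state = init_clusters(Z, 2, seed=0)
        assert sorted(state.centers.ravel()) == [0.0, 1.0]
        assert np.all(state.scale_diags == state.clamp_floor)

    def test_toy_data_centers_near_group_means(self):
        ds = gen_toy_linear(ToySpec(seed=3))
        state = init_clusters(ds.true_weights, 2, seed=0)
        order = np.argsort(state.centers.mean(axis=1))
        expected = np.stack([np.full(30, 1.0), np.full(30, 1.5)])
        assert np.max(np.abs(state.centers[order] - expected)) < 0.05

    def test_deterministic(self, rng):
        Z = rng.normal(size=(40, 3))
        a = init_clusters(Z, 3, seed=7)
        b = init_clusters(Z, 3, seed=7)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.scale_diags, b.scale_diags)

    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="at least"):
            init_clusters(np.zeros((2, 1)), 3, seed=0)


class TestMixtureLogLikelihood:
    def test_single_component_equals_density_sum(self, rng):
        Z = rng.normal(size=(10, 2))
        state = TMixtureState(
            centers=np.zeros((1, 2)), scale_diags=np.ones((1, 2)), dof=2.1
        )
        expected = sum(
            t_log_density(z, state.centers[0], state.scale_diags[0], 2.1)
            for z in Z
        )
        assert mixture_log_likelihood(Z, state) == pytest.approx(expected, rel=1e-12)

    def test_em_cycle_never_decreases(self, rng, two_component_state):
        Z, _ = gen_tmm_samples(two_component_state, 200, seed=5)
        state = TMixtureState(
            centers=rng.normal(size=(2, 3)),
            scale_diags=rng.uniform(0.5, 2.0, size=(2, 3)),
            dof=2.1,
            clamp_floor=1e-300,
        )
        before = mixture_log_likelihood(Z, state)
        Q, U = e_step(Z, state)
        state = m_step(Z, Q, U, state)
        after = mixture_log_likelihood(Z, state)
        assert after >= before - 1e-8

    def test_quadrature_backed_two_point_instance(self):
        # N=2, K=1: mixture likelihood against numerically integrated densities
        state = TMixtureState(
            centers=np.array([[0.0], [3.0]]),
            scale_diags=np.array([[1.0], [2.0]]),
            dof=2.1,
        )
        Z = np.array([[0.5], [2.0]])
        nu = state.dof

        def t_pdf_quad(z, mu, sig):
            def integrand(u):
                dens = norm.pdf(z, mu, np.sqrt(sig / u))
                gamma_pdf = (
                    (nu / 2) ** (nu / 2)
                    / math.gamma(nu / 2)
                    * u ** (nu / 2 - 1)
                    * np.exp(-nu / 2 * u)
                )
                return dens * gamma_pdf

            return quad(integrand, 0, np.inf)[0]

        expected = sum(
            np.log(
                0.5 * t_pdf_quad(z[0], 0.0, 1.0) + 0.5 * t_pdf_quad(z[0], 3.0, 2.0)
            )
            for z in Z
        )
        assert mixture_log_likelihood(Z, state) == pytest.approx(expected, rel=1e-6)


class TestMapAssign:
    @pytest.mark.parametrize(
        "Q,expected",
        [
            ([[0.9, 0.1]], [0]),
            ([[0.5, 0.5]], [0]),  # tie broken toward lowest index
            ([[0.1, 0.2, 0.7], [0.3, 0.3, 0.3]], [2, 0]),
        ],
    )
    def test_labels(self, Q, expected):
        np.testing.assert_array_equal(map_assign(np.array(Q)), expected)

    def test_one_hot_recovers_labels(self, rng):
        labels = rng.integers(0, 4, size=25)
        np.testing.assert_array_equal(map_assign(np.eye(4)[labels]), labels)


# ---------------------------------------------------------------------------
# state validation and estimator


class TestTMixtureState:
    def test_rejects_dof_at_most_two(self):
        with pytest.raises(ValueError, match="dof"):
            TMixtureState(np.zeros((1, 1)), np.ones((1, 1)), dof=2.0)

    def test_rejects_scale_below_floor(self):
        with pytest.raises(ValueError, match="clamp_floor"):
            TMixtureState(
                np.zeros((1, 2)), np.array([[1.0, 1e-9]]), dof=2.1, clamp_floor=1e-6
            )

    def test_round_trip_dict(self, two_component_state):
        st = TMixtureState.from_dict(two_component_state.to_dict())
        np.testing.assert_array_equal(st.centers, two_component_state.centers)
        assert st.dof == two_component_state.dof


class TestStudentTMixtureEstimator:
    def test_recovers_separated_blobs(self, rng):
        Z = np.vstack(
            [rng.normal(0, 0.2, size=(60, 2)), rng.normal(4, 0.2, size=(40, 2))]
        )
        est = StudentTMixture(n_clusters=2, random_state=0).fit(Z)
        labels = est.labels_
        # one cluster holds exactly the first 60 points
        assert len(set(labels[:60])) == 1 and len(set(labels[60:])) == 1
        assert labels[0] != labels[-1]
        assert est.predict(Z[:3]).shape == (3,)
        assert est.predict_proba(Z).shape == (100, 2)

    def test_sklearn_params_round_trip(self):
        est = StudentTMixture(n_clusters=5, dof=3.0)
        params = est.get_params()
        assert params["n_clusters"] == 5
        est2 = StudentTMixture(**params)
        assert est2.dof == 3.0
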