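import numpy as np
import pytest

from decembr.mixture import TMixtureState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_component_state():
    """Well-separated 2-component mixture in K=3."""
    return TMixtureState(
        centers=np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 5.0]]),
        scale_diags=np.array([[1.0, 0.5, 2.0], [0.3, 1.0, 0.7]]),
        dof=2.1,
    )


def naive_t_log_density(z, mu, sig, nu):
    """Independent loop implementation of the diagonal-scale t log-density."""
    from scipy.special import gammaln

    k = len(z)
    delta2 = 0.0
    logdet = 0.0
    for zz, m, s in zip(z, mu, sig):
        delta2 += (zz - m) ** 2 / s
        logdet += np.log(s)
    return (
        gammaln((nu + k) / 2)
        - gammaln(nu / 2)
        - k / 2 * np.log(nu * np.pi)
        - 0.5 * logdet
        - (nu + k) / 2 * np.log(1 + delta2 / nu)
    )


def naive_e_step(Z, state):
    """Loop-based E-step oracle: normalized densities and latent scales."""
    N, K = Z.shape
    J = state.num_clusters
    Q = np.zeros((N, J))
    U = np.zeros((N, J))
    for i in range(N):
        dens = np.array(
            [
                np.exp(
                    naive_t_log_density(
                        Z[i], state.centers[j], state.scale_diags[j], state.dof
                    )
                )
                for j in range(J)
            ]
        )
        Q[i] = dens / dens.sum()
        for j in range(J):
            d2 = sum(
                (Z[i, k] - state.centers[j, k]) ** 2 / state.scale_diags[j, k]
                for k in range(K)
            )
            U[i, j] = (state.dof + K) / (state.dof + d2)
    return Q, U


def naive_m_step(Z, Q, U, state):
    """Loop-based M-step oracle (no clamping applied)."""
    N, K = Z.shape
    J = state.num_clusters
    centers = np.zeros((J, K))
    scales = np.zeros((J, K))
    for j in range(J):
        wsum = sum(Q[i, j] * U[i, j] for i in range(N))
        for k in range(K):
            centers[j, k] = (
                sum(Q[i, j] * U[i, j] * Z[i, k] for i in range(N)) / wsum
            )
        qsum = sum(Q[i, j] for i in range(N))
        for k in range(K):
            scales[j, k] = (
                sum(
                    Q[i, j] * U[i, j] * (Z[i, k] - centers[j, k]) ** 2
                    for i in range(N)
                )
                / qsum
            )
    return centers, scales


def naive_target(Q):
    """Loop-based target-distribution oracle."""
    N, J = Q.shape
    f = [sum(Q[i, j] for i in range(N)) for j in range(J)]
    P = np.zeros_like(Q)
    for i in range(N):
        w = [Q[i, j] ** 2 / f[j] for j in range(J)]
        for j in range(J):
            P[i, j] = w[j] / sum(w)
    return P


def pair_counting_ari(a, b):
    """From-scratch pair-counting ARI (Hubert & Arabie form)."""
    n = len(a)
    s11 = s00 = s10 = s01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a and same_b:
                s11 += 1
            elif same_a:
                s10 += 1
            elif same_b:
                s01 += 1
            else:
                s00 += 1
    num = 2.0 * (s11 * s00 - s10 * s01)
    den = (s11 + s10) * (s10 + s00) + (s11 + s01) * (s01 + s00)
    return num / den if den else 1.0
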