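"""Student's-t mixture model with diagonal scale matrices.

This module implements the clustering half of DECEMber: soft assignments
under a multivariate Student's-t mixture, the latent Gamma scale variables
of the shape-rate representation, closed-form EM updates of cluster centers
and (diagonal) scale matrices, the sharpened target distribution of deep
embedding clustering, and the KL clustering loss.

The mixture has equal, fixed mixing weights 1/J and a single shared degrees
of freedom ``nu`` (default 2.1, just above the threshold nu > 2 where the
variance nu/(nu-2)*Sigma of a t-distribution exists). Cluster centers and
scales are never touched by gradient descent; they are updated only through
the EM steps here.

All densities and responsibilities are computed in log space; responsibilities
are normalized with log-sum-exp. Scale diagonals are clamped from below at a
configurable floor to keep high-dimensional fits numerically stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

__all__ = [
    "TMixtureState",
    "DegenerateClusterError",
    "t_log_density",
    "e_step",
    "m_step",
    "target_distribution",
    "clustering_loss",
    "init_clusters",
    "mixture_log_likelihood",
    "map_assign",
    "StudentTMixture",
]

_ROW_SUM_TOL = 1e-9


class DegenerateClusterError(RuntimeError):
    """Raised when a cluster receives (numerically) zero total responsibility."""

    def __init__(self, cluster: int):
        self.cluster = cluster
        super().__init__(f"cluster {cluster} has zero total responsibility")


@dataclass(frozen=True)
class TMixtureState:
    """Parameters of a J-component Student's-t mixture with diagonal scales.

    Attributes
    ----------
    centers : (J, K) ndarray
        Cluster centers mu_j.
    scale_diags : (J, K) ndarray
        Diagonal entries of the scale matrices Sigma_j; strictly positive and
        at least ``clamp_floor``.
    dof : float
        Shared degrees of freedom nu; must exceed 2 so the component variance
        nu/(nu-2) * Sigma is defined.
    clamp_floor : float
        Lower bound applied elementwise to ``scale_diags``.
    """

    centers: NDArray[np.float64]
    scale_diags: NDArray[np.float64]
    dof: float = 2.1
    clamp_floor: float = 1e-6

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=np.float64)
        scales = np.asarray(self.scale_diags, dtype=np.float64)
        if centers.ndim != 2 or centers.shape != scales.shape:
            raise ValueError(
                f"centers {centers.shape} and scale_diags {scales.shape} "
                "must be 2-D arrays of identical shape"
            )
        if not self.dof > 2:
            raise ValueError(f"dof must exceed 2 (got {self.dof})")
        if not self.clamp_floor > 0:
            raise ValueError("clamp_floor must be positive")
        if np.any(scales < self.clamp_floor):
            raise ValueError("every scale_diag entry must be >= clamp_floor")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "scale_diags", scales)

    @property
    def num_clusters(self) -> int:
        return self.centers.shape[0]

    @property
    def num_features(self) -> int:
        return self.centers.shape[1]

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "scale_diags": self.scale_diags.tolist(),
            "dof": float(self.dof),
            "num_clusters": int(self.num_clusters),
            "clamp_floor": float(self.clamp_floor),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TMixtureState":
        return cls(
            centers=np.asarray(d["centers"], dtype=np.float64),
            scale_diags=np.asarray(d["scale_diags"], dtype=np.float64),
            dof=float(d["dof"]),
            clamp_floor=float(d["clamp_floor"]),
        )


def _row_softmax(logits: NDArray[np.float64]) -> NDArray[np.float64]:
    """Max-subtracted row softmax.

    Both Q (E-step) and P (target distribution) are normalized through this
    one code path so that tied logits produce bitwise-identical rows — in the
    degenerate all-centers-equal configuration Q and P are then exactly equal
    and the KL clustering loss is exactly zero.
    """
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


def _as_2d(Z: ArrayLike) -> NDArray[np.float64]:
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim == 1:
        Z = Z[None, :]
    if Z.ndim != 2:
        raise ValueError(f"embedding matrix must be 2-D, got shape {Z.shape}")
    return Z


def t_log_density(
    z: ArrayLike,
    center: ArrayLike,
    scale_diag: ArrayLike,
    dof: float,
) -> float:
    """Log-density of a multivariate t-distribution with diagonal scale.

    Computed entirely in log space: log-gamma terms, the log-determinant as a
    sum of log scale entries, and the quadratic form as a per-dimension sum.

        log f_t(z) = lgamma((nu+K)/2) - lgamma(nu/2) - (K/2) log(nu pi)
                     - (1/2) sum_k log sigma2_k
                     - ((nu+K)/2) log(1 + delta2/nu)

    with delta2 = sum_k (z_k - mu_k)^2 / sigma2_k.
    """
    z = np.asarray(z, dtype=np.float64)
    center = np.asarray(center, dtype=np.float64)
    scale_diag = np.asarray(scale_diag, dtype=np.float64)
    if np.any(scale_diag <= 0):
        raise ValueError("scale_diag entries must be strictly positive")
    if not dof > 0:
        raise ValueError("dof must be positive")
    k = z.shape[-1]
    delta2 = np.sum((z - center) ** 2 / scale_diag, axis=-1)
    return (
        gammaln((dof + k) / 2.0)
        - gammaln(dof / 2.0)
        - 0.5 * k * np.log(dof * np.pi)
        - 0.5 * np.sum(np.log(scale_diag), axis=-1)
        - 0.5 * (dof + k) * np.log1p(delta2 / dof)
    )


def _component_log_densities(
    Z: NDArray[np.float64], state: TMixtureState
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Return (N, J) log f_t(z_i; mu_j, Sigma_j, nu) and (N, J) quadratic forms."""
    if Z.shape[1] != state.num_features:
        raise ValueError(
            f"embeddings have {Z.shape[1]} features, state expects "
            f"{state.num_features}"
        )
    diff = Z[:, None, :] - state.centers[None, :, :]  # (N, J, K)
    delta2 = np.sum(diff**2 / state.scale_diags[None, :, :], axis=-1)  # (N, J)
    k = state.num_features
    nu = state.dof
    log_norm = (
        gammaln((nu + k) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * k * np.log(nu * np.pi)
        - 0.5 * np.sum(np.log(state.scale_diags), axis=-1)  # (J,)
    )
    log_dens = log_norm[None, :] - 0.5 * (nu + k) * np.log1p(delta2 / nu)
    return log_dens, delta2


def e_step(
    Z: ArrayLike, state: TMixtureState
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """E-step: soft assignments Q and latent scales U.

    q_ij is the posterior responsibility of component j for embedding z_i
    under equal mixing weights, computed via log-sum-exp:

        q_ij = f_t(z_i; mu_j, Sigma_j, nu) / sum_j' f_t(z_i; mu_j', ...)

    u_ij is the posterior mean of the Gamma latent variable of the shape-rate
    representation:

        u_ij = (nu + K) / (nu + (z_i - mu_j)^T Sigma_j^{-1} (z_i - mu_j))

    Returns
    -------
    Q : (N, J) row-stochastic ndarray
    U : (N, J) strictly positive ndarray
    """
    Z = _as_2d(Z)
    log_dens, delta2 = _component_log_densities(Z, state)
    Q = _row_softmax(log_dens)
    U = (state.dof + state.num_features) / (state.dof + delta2)
    return Q, U


def m_step(
    Z: ArrayLike,
    Q: ArrayLike,
    U: ArrayLike,
    state: TMixtureState,
) -> TMixtureState:
    """M-step: closed-form updates of centers and diagonal scales.

        mu_j    = sum_i q_ij u_ij z_i / sum_i q_ij u_ij
        Sigma_j = diag[ sum_i q_ij u_ij (z_i - mu_j)(z_i - mu_j)^T / sum_i q_ij ]

    The scale update uses the freshly updated mu_j, then every diagonal entry
    is clamped from below at ``state.clamp_floor``.

    Raises
    ------
    DegenerateClusterError
        If some cluster's total responsibility sum_i q_ij is zero.
    """
    Z = _as_2d(Z)
    Q = np.asarray(Q, dtype=np.float64)
    U = np.asarray(U, dtype=np.float64)
    if Q.shape != (Z.shape[0], state.num_clusters) or U.shape != Q.shape:
        raise ValueError("Q and U must be (N, J) arrays conforming to Z and state")
    q_sums = Q.sum(axis=0)  # (J,)
    for j, s in enumerate(q_sums):
        if s <= 0:
            raise DegenerateClusterError(j)
    W = Q * U  # (N, J)
    w_sums = W.sum(axis=0)  # (J,)
    centers = (W.T @ Z) / w_sums[:, None]  # (J, K)
    diff2 = (Z[:, None, :] - centers[None, :, :]) ** 2  # (N, J, K)
    scales = np.einsum("nj,njk->jk", W, diff2) / q_sums[:, None]
    scales = np.maximum(scales, state.clamp_floor)
    return replace(state, centers=centers, scale_diags=scales)


def target_distribution(Q: ArrayLike) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Sharpened, frequency-normalized target distribution P.

        f_j  = sum_i q_ij
        p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j')

    Squaring raises confident assignments and the division by the soft cluster
    frequency f_j stops large clusters from dominating the loss.

    Returns
    -------
    P : (N, J) row-stochastic ndarray
    f : (J,) cluster frequencies (column sums of Q)
    """
    Q = np.asarray(Q, dtype=np.float64)
    f = Q.sum(axis=0)
    if np.any(f <= 0):
        j = int(np.argmin(f))
        raise DegenerateClusterError(j)
    with np.errstate(divide="ignore"):  # q_ij = 0 (hard assignment) is fine
        log_w = 2.0 * np.log(Q) - np.log(f)[None, :]
    P = _row_softmax(log_w)
    return P, f


def clustering_loss(Q: ArrayLike, P: ArrayLike) -> float:
    """KL clustering loss sum_ij p_ij log(p_ij / q_ij).

    P is the (constant) target; 0 * log(0/q) is treated as 0. If some q_ij is
    zero where p_ij > 0 the loss is infinite; a warning is emitted and +inf
    returned.
    """
    Q = np.asarray(Q, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same shape")
    support = P > 0
    if np.any(Q[support] == 0):
        warnings.warn(
            "q_ij = 0 where p_ij > 0: KL divergence is infinite", RuntimeWarning
        )
        return float("inf")
    vals = np.zeros_like(P)
    vals[support] = P[support] * (np.log(P[support]) - np.log(Q[support]))
    # KL(P||Q) >= 0 by Gibbs' inequality; guard against rounding at P ~= Q
    return max(0.0, float(vals.sum()))


def init_clusters(
    Z: ArrayLike,
    J: int,
    seed: int,
    *,
    dof: float = 2.1,
    clamp_floor: float = 1e-6,
    n_restarts: int = 10,
    max_retries: int = 5,
) -> TMixtureState:
    """Initialize the mixture from seeded k-means.

    Centers are the best-inertia k-means centroids over ``n_restarts``
    restarts; scale diagonals are the per-dimension within-cluster variances
    of the points assigned to each centroid, clamped at ``clamp_floor``.
    Empty k-means clusters trigger a re-seeded retry up to ``max_retries``.
    """
    Z = _as_2d(Z)
    n = Z.shape[0]
    if n < J:
        raise ValueError(f"need at least J={J} embeddings, got N={n}")
    for attempt in range(max_retries):
        km = KMeans(n_clusters=J, n_init=n_restarts, random_state=seed + attempt)
        labels = km.fit_predict(Z)
        counts = np.bincount(labels, minlength=J)
        if np.all(counts > 0):
            break
    else:
        raise RuntimeError(f"k-means produced an empty cluster in {max_retries} tries")
    centers = km.cluster_centers_.astype(np.float64)
    scales = np.empty_like(centers)
    for j in range(J):
        members = Z[labels == j]
        scales[j] = members.var(axis=0)
    scales = np.maximum(scales, clamp_floor)
    return TMixtureState(
        centers=centers, scale_diags=scales, dof=dof, clamp_floor=clamp_floor
    )


def mixture_log_likelihood(Z: ArrayLike, state: TMixtureState) -> float:
    """Total log-likelihood sum_i log[(1/J) sum_j f_t(z_i; mu_j, Sigma_j, nu)].

    Mixing weights are the model's fixed 1/J; evaluated with log-sum-exp.
    """
    Z = _as_2d(Z)
    log_dens, _ = _component_log_densities(Z, state)
    return float(
        np.sum(logsumexp(log_dens - np.log(state.num_clusters), axis=1))
    )


def map_assign(Q: ArrayLike) -> NDArray[np.int64]:
    """MAP labels: argmax over clusters, ties broken toward the lowest index."""
    Q = np.asarray(Q, dtype=np.float64)
    return np.argmax(Q, axis=1).astype(np.int64)


def reseed_empty_clusters(
    Z: NDArray[np.float64],
    Q: NDArray[np.float64],
    state: TMixtureState,
    threshold_per_point: float = 1e-8,
) -> tuple[TMixtureState, bool]:
    """Re-initialize clusters whose total responsibility has collapsed.

    A cluster j with sum_i q_ij < threshold_per_point * N gets its center moved
    to the embedding with the lowest maximum responsibility (the point worst
    explained by any current component); a warning is logged. Returns the
    (possibly) updated state and whether a reseed happened.
    """
    col = Q.sum(axis=0)
    thresh = threshold_per_point * Z.shape[0]
    dead = np.nonzero(col < thresh)[0]
    if dead.size == 0:
        return state, False
    centers = state.centers.copy()
    order = np.argsort(Q.max(axis=1))  # least-well-explained first
    for rank, j in enumerate(dead):
        centers[j] = Z[order[rank % len(order)]]
        warnings.warn(
            f"cluster {j} had vanishing responsibility; re-seeded its center",
            RuntimeWarning,
        )
    return replace(state, centers=centers), True


class StudentTMixture(ClusterMixin, BaseEstimator):
    """Student's-t mixture clustering fitted by EM.

    A scikit-learn-style estimator around the EM machinery above: k-means
    initialization, alternating E/M updates with fixed equal mixing weights
    1/J and fixed shared degrees of freedom, diagonal scale matrices clamped
    at ``clamp_floor``.

    Parameters
    ----------
    n_clusters : int
        Number of mixture components J.
    dof : float, default 2.1
        Degrees of freedom nu; must exceed 2.
    clamp_floor : float, default 1e-6
        Elementwise lower bound on the scale diagonals.
    max_iter : int, default 100
        Maximum EM cycles.
    tol : float, default 1e-8
        Absolute log-likelihood improvement below which EM stops.
    random_state : int, default 0
        Seed for the k-means initialization.

    Attributes
    ----------
    state_ : TMixtureState
        Fitted centers, scale diagonals, dof.
    labels_ : (N,) ndarray
        MAP labels of the training embeddings.
    log_likelihood_ : float
        Final total log-likelihood.
    n_iter_ : int
        EM cycles run.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        dof: float = 2.1,
        clamp_floor: float = 1e-6,
        max_iter: int = 100,
        tol: float = 1e-8,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.dof = dof
        self.clamp_floor = clamp_floor
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: ArrayLike, y=None) -> "StudentTMixture":
        Z = _as_2d(X)
        state = init_clusters(
            Z,
            self.n_clusters,
            seed=self.random_state,
            dof=self.dof,
            clamp_floor=self.clamp_floor,
        )
        prev = -np.inf
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            Q, U = e_step(Z, state)
            state, _ = reseed_empty_clusters(Z, Q, state)
            state = m_step(Z, Q, U, state)
            ll = mixture_log_likelihood(Z, state)
            if ll - prev < self.tol and n_iter > 1:
                prev = ll
                break
            prev = ll
        self.state_ = state
        Q, _ = e_step(Z, state)
        self.labels_ = map_assign(Q)
        self.log_likelihood_ = prev
        self.n_iter_ = n_iter
        return self

    def predict_proba(self, X: ArrayLike) -> NDArray[np.float64]:
        Q, _ = e_step(X, self.state_)
        return Q

    def predict(self, X: ArrayLike) -> NDArray[np.int64]:
        return map_assign(self.predict_proba(X))

    def score(self, X: ArrayLike, y=None) -> float:
        """Mean per-sample mixture log-likelihood."""
        Z = _as_2d(X)
        return mixture_log_likelihood(Z, self.state_) / Z.shape[0]
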