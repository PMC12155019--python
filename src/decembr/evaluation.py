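"""Clustering-consistency and model-performance metrics.

Covers the evaluation protocol around the clustering experiments: the
Adjusted Rand Index and cross-seed consistency matrices, GMM and k-means
baselines (diagonal covariance, 1e-6 regularization, fixed clustering seed),
Hungarian label alignment for confusion matrices, mean per-neuron Pearson
correlation between predicted and observed responses, and the t-SNE
visualization protocol (perplexity N/100, learning rate 1, early
exaggeration N/10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

__all__ = [
    "PartitionSet",
    "adjusted_rand_index",
    "consistency_across_seeds",
    "gmm_baseline",
    "kmeans_baseline",
    "align_and_confuse",
    "mean_neuron_correlation",
    "tsne_embed",
]


@dataclass
class PartitionSet:
    """A collection of labelings of the same neurons, tagged by provenance."""

    labelings: list[NDArray[np.int64]] = field(default_factory=list)
    tags: list[tuple] = field(default_factory=list)

    def add(self, labels: ArrayLike, method: str = "", seed: int = 0, J: int = 0):
        labels = np.asarray(labels, dtype=np.int64)
        if self.labelings and labels.shape != self.labelings[0].shape:
            raise ValueError("all labelings must cover the same neuron index set")
        self.labelings.append(labels)
        self.tags.append((method, seed, J))
        return self


def adjusted_rand_index(a: ArrayLike, b: ArrayLike) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    1 iff the partitions are identical (up to label permutation); expectation
    0 for independent random partitions.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))


def consistency_across_seeds(
    partitions: PartitionSet | list,
) -> tuple[float, NDArray[np.float64]]:
    """Mean pairwise ARI and the full (symmetric, unit-diagonal) ARI matrix."""
    labelings = (
        partitions.labelings if isinstance(partitions, PartitionSet) else list(partitions)
    )
    m = len(labelings)
    if m < 2:
        raise ValueError("need at least 2 partitions")
    mat = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = adjusted_rand_index(labelings[i], labelings[j])
    mean = float(mat[np.triu_indices(m, k=1)].mean())
    return mean, mat


def gmm_baseline(Z: ArrayLike, J: int, seed: int) -> NDArray[np.int64]:
    """Diagonal-covariance GMM with 1e-6 covariance regularization."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[0] < J:
        raise ValueError(f"need at least J={J} points")
    gmm = GaussianMixture(
        n_components=J,
        covariance_type="diag",
        reg_covar=1e-6,
        random_state=seed,
    )
    return gmm.fit_predict(Z).astype(np.int64)


def kmeans_baseline(Z: ArrayLike, J: int, seed: int) -> NDArray[np.int64]:
    """k-means labels at a fixed seed (single init, so seed sensitivity of
    the initialization is surfaced rather than averaged away)."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[0] < J:
        raise ValueError(f"need at least J={J} points")
    km = KMeans(n_clusters=J, n_init=1, random_state=seed)
    return km.fit_predict(Z).astype(np.int64)


def align_and_confuse(
    pred: ArrayLike, truth: ArrayLike
) -> NDArray[np.int64]:
    """Confusion matrix with predicted columns permuted to maximize the trace.

    Rows are true classes, columns the (Hungarian-aligned) predicted
    clusters. Row and column sums are preserved by the permutation.
    """
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    n_true = int(truth.max()) + 1
    n_pred = int(pred.max()) + 1
    n = max(n_true, n_pred)
    conf = np.zeros((n, n), dtype=np.int64)
    np.add.at(conf, (truth, pred), 1)
    _, col_perm = linear_sum_assignment(-conf)
    return conf[:, col_perm]


def mean_neuron_correlation(predicted: ArrayLike, observed: ArrayLike) -> float:
    """Mean over neurons of the per-neuron Pearson r across images.

    Neurons with constant predicted or observed responses are excluded with
    a warning (their correlation is undefined).
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape:
        raise ValueError("shape mismatch")
    if predicted.shape[0] < 2:
        raise ValueError("need at least 2 images")
    ps = predicted.std(axis=0)
    os_ = observed.std(axis=0)
    keep = (ps > 0) & (os_ > 0)
    if not np.any(keep):
        raise ValueError("all neurons are constant; correlation undefined")
    if not np.all(keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} constant neurons from correlation",
            RuntimeWarning,
        )
    p = predicted[:, keep] - predicted[:, keep].mean(axis=0)
    o = observed[:, keep] - observed[:, keep].mean(axis=0)
    r = (p * o).mean(axis=0) / (p.std(axis=0) * o.std(axis=0))
    return float(r.mean())


def tsne_embed(Z: ArrayLike, seed: int) -> NDArray[np.float64]:
    """2-D t-SNE with perplexity N/100, learning rate 1, early exaggeration
    N/10 — the visualization protocol for large embedding sets. Figures only;
    never used for metrics."""
    Z = np.asarray(Z, dtype=np.float64)
    n = Z.shape[0]
    if n < 300:
        raise ValueError("t-SNE protocol requires N >= 300 (perplexity N/100)")
    from sklearn.manifold import TSNE

    tsne = TSNE(
        n_components=2,
        perplexity=n / 100.0,
        learning_rate=1.0,
        early_exaggeration=n / 10.0,
        init="pca",
        random_state=seed,
    )
    return tsne.fit_transform(Z)
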