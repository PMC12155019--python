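"""Synthetic dataset generators.

Three generators cover everything the in-scope experiments need:

* :func:`gen_toy_linear` — the linear-neuron toy population: 8000 stimuli
  uniform on (-1, 1)^30 and 2500 noise-free linear neurons in two groups
  (2000 with weights 1 + U(-1/300, 1/300) per coordinate, 500 with weights
  1.5 + U(-1/120, 1/120)), the setting in which vanilla deep embedding
  clustering collapses while the EM-refined t-mixture variant recovers the
  planted groups.
* :func:`gen_poisson_population` — populations of Poisson-spiking neurons
  whose readout weights are drawn from planted clusters; rates come from a
  fixed, known core-readout model applied to white-noise images.
* :func:`gen_tmm_samples` — raw draws from a Student's-t mixture via the
  shape-rate construction u ~ Gamma(nu/2, nu/2), z ~ N(mu_j, Sigma_j / u).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .data import StimulusResponseDataset
from .mixture import TMixtureState
from .models import CoreReadoutModel, _softplus
from .rng import seed_stream

__all__ = [
    "ToySpec",
    "PlantedPopulationSpec",
    "gen_toy_linear",
    "gen_poisson_population",
    "gen_tmm_samples",
]


@dataclass(frozen=True)
class ToySpec:
    """Specification of the linear-neuron toy dataset (defaults are canonical)."""

    n_stimuli: int = 8000
    dim: int = 30
    n_neurons: int = 2500
    group_sizes: tuple[int, int] = (2000, 500)
    group_centers: tuple[float, float] = (1.0, 1.5)
    noise_half_widths: tuple[float, float] = (1.0 / 300.0, 1.0 / 120.0)
    seed: int = 0

    def __post_init__(self):
        if sum(self.group_sizes) != self.n_neurons:
            raise ValueError("group sizes must sum to n_neurons")


@dataclass(frozen=True)
class PlantedPopulationSpec:
    """Planted-cluster Poisson population.

    ``separation`` is the minimum distance between cluster centers in pooled
    within-cluster scale units (``spread``); ``mean_rate`` is the per-neuron
    average spike count the rates are normalized to.
    """

    n_neurons: int = 300
    dim: int = 8
    n_clusters: int = 3
    separation: float = 4.0
    spread: float = 0.15
    image_size: int = 16
    n_stimuli: int = 1000
    mean_rate: float = 2.0
    rate_gain: float = 2.0  # std of the per-neuron pre-activation drive
    seed: int = 0


def gen_toy_linear(spec: ToySpec = ToySpec()) -> StimulusResponseDataset:
    """Toy linear-neuron dataset with noise-free responses y = Z x."""
    rng = seed_stream(spec.seed, "toy-data")
    X = rng.uniform(-1.0, 1.0, size=(spec.n_stimuli, spec.dim))
    parts = []
    labels = []
    for g, (size, center, hw) in enumerate(
        zip(spec.group_sizes, spec.group_centers, spec.noise_half_widths)
    ):
        eps = rng.uniform(-hw, hw, size=(size, spec.dim))
        parts.append(center + eps)
        labels.append(np.full(size, g, dtype=np.int64))
    Z = np.vstack(parts)
    Y = X @ Z.T  # noise-free linear responses
    return StimulusResponseDataset(
        stimuli=X,
        responses=Y,
        true_labels=np.concatenate(labels),
        true_weights=Z,
    )


def _planted_centers(
    rng: np.random.Generator, n_clusters: int, dim: int, min_distance: float
) -> NDArray[np.float64]:
    """Random directions rescaled so the closest center pair sits at
    ``min_distance``; degenerate at zero distance by construction."""
    raw = rng.normal(size=(n_clusters, dim))
    if min_distance == 0:
        return np.zeros((n_clusters, dim))
    d = np.linalg.norm(raw[:, None, :] - raw[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return raw * (min_distance / d.min())


def gen_poisson_population(
    spec: PlantedPopulationSpec = PlantedPopulationSpec(),
) -> StimulusResponseDataset:
    """Poisson population with readout weights drawn from planted clusters.

    True weights are cluster center + N(0, spread^2) noise; receptive-field
    positions are uniform in [-1, 1]^2; rates come from a fixed randomly
    initialized convolutional core applied to white-noise images, normalized
    per neuron to the spec's mean rate; responses are Poisson counts.
    """
    rng_w = seed_stream(spec.seed, "population-weights")
    rng_s = seed_stream(spec.seed, "population-stimuli")
    rng_r = seed_stream(spec.seed, "population-responses")
    rng_c = seed_stream(spec.seed, "population-core")

    centers = _planted_centers(
        rng_w, spec.n_clusters, spec.dim, spec.separation * spec.spread
    )
    labels = np.repeat(
        np.arange(spec.n_clusters), int(np.ceil(spec.n_neurons / spec.n_clusters))
    )[: spec.n_neurons]
    true_weights = centers[labels] + rng_w.normal(
        scale=spec.spread, size=(spec.n_neurons, spec.dim)
    )

    model = CoreReadoutModel.init(spec.n_neurons, spec.dim, rng_c)
    model.params["weights"] = true_weights
    true_positions = rng_w.uniform(-1.0, 1.0, size=(spec.n_neurons, 2))
    model.params["positions"] = true_positions

    X = rng_s.normal(size=(spec.n_stimuli, spec.image_size, spec.image_size, 1))
    fmap = model.core_features(X)
    from .models import bilinear_interpolate

    pre = np.empty((spec.n_stimuli, spec.n_neurons))
    for b in range(spec.n_stimuli):
        phi, _ = bilinear_interpolate(fmap[b], model.params["positions"])
        pre[b] = np.einsum("nk,nk->n", phi, true_weights)
    # standardize the drive per neuron so every neuron is strongly
    # stimulus-modulated regardless of where its receptive field landed
    std = pre.std(axis=0)
    if np.any(std == 0):
        raise ValueError("rate construction produced an unmodulated neuron")
    pre = (pre - pre.mean(axis=0)) / std * spec.rate_gain
    rates = _softplus(pre)
    col_means = rates.mean(axis=0)
    if np.any(col_means <= 0):
        raise ValueError("rate construction produced a nonpositive mean rate")
    rates = rates * (spec.mean_rate / col_means)  # exact per-neuron mean rate
    responses = rng_r.poisson(rates).astype(np.float64)
    return StimulusResponseDataset(
        stimuli=X,
        responses=responses,
        true_labels=labels,
        true_weights=true_weights,
        nonnegative=True,
        true_positions=true_positions,
    )


def gen_tmm_samples(
    state: TMixtureState, n: int, seed: int
) -> tuple[NDArray[np.float64], NDArray[np.int64]]:
    """Exact draws from the t-mixture via the shape-rate construction.

    Components are chosen uniformly (the model's fixed 1/J weights); for each
    draw u ~ Gamma(nu/2, rate nu/2) and z ~ N(mu_j, Sigma_j / u).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed_stream(seed, "tmm-samples")
    labels = rng.integers(0, state.num_clusters, size=n)
    u = rng.gamma(shape=state.dof / 2.0, scale=2.0 / state.dof, size=n)
    std = np.sqrt(state.scale_diags[labels] / u[:, None])
    Z = state.centers[labels] + rng.normal(size=(n, state.num_features)) * std
    return Z, labels.astype(np.int64)
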