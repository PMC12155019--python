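"""Joint training: pretraining, cluster init, and the E/M/gradient loop.

The main entry point is :func:`decembr_fit`, which implements the DECEMber
training loop: after pretraining a predictive model on its own loss and
initializing a Student's-t mixture on the embeddings with k-means, every
minibatch performs

1. an E-step over all N embeddings (soft assignments Q, latent scales U),
2. an M-step over all N embeddings (closed-form center/scale updates),
3. one gradient step on ``model_loss_weight * L_model(batch) +
   beta * L_cluster`` with the target distribution P held constant.

Cluster parameters receive no gradients — they move only through EM.

:func:`dec_unit_scale_fit` is the vanilla-DEC ablation: the same loop with
the soft-assignment kernel fixed at unit scale (t-kernel with nu = 1) and
center updates that are plain responsibility-weighted means (the latent
scales u are identically 1 and the scale matrices are never adapted). On
close, imbalanced clusters this variant collapses all centers to a single
point — the degenerate KL optimum — which is the failure mode that motivates
the adaptive scale matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
from numpy.typing import NDArray

from .data import StimulusResponseDataset
from .mixture import (
    TMixtureState,
    clustering_loss,
    e_step,
    init_clusters,
    map_assign,
    m_step,
    reseed_empty_clusters,
    target_distribution,
)
from .models import (
    CoreReadoutModel,
    LinearNeuronModel,
    mse_loss,
    poisson_loss,
    poisson_loss_grad,
)
from .rng import seed_stream

__all__ = [
    "TrainConfig",
    "TrainResult",
    "DECState",
    "DivergenceError",
    "pretrain",
    "decembr_fit",
    "dec_unit_scale_fit",
    "beta_heuristic",
    "build_model",
    "DECEMber",
]

MODEL_KINDS = ("linear-toy", "core-readout")


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class TrainConfig:
    """Configuration of a DECEMber run.

    ``beta`` is the clustering-loss weight; ``None`` selects it at
    clustering-start with :func:`beta_heuristic`. ``total_epochs`` counts
    pretraining plus clustering epochs, so the clustering phase runs
    ``total_epochs - pretrain_epochs`` epochs. ``model_loss_weight`` scales
    the predictive loss during the clustering phase (0 gives the KL-only
    protocol used by the toy experiments).
    """

    beta: float | None = None
    pretrain_epochs: int = 25
    total_epochs: int = 50
    learning_rate: float = 0.01
    batch_size: int = 256
    num_clusters: int = 2
    dof: float = 2.1
    clamp_floor: float = 1e-6
    seed: int = 0
    model_kind: str = "linear-toy"
    model_loss_weight: float = 1.0
    embedding_dim: int = 8
    weight_decay: float = 1e-4
    val_fraction: float = 0.1
    early_stop_patience: int | None = None
    lr_decay_factor: float = 0.5
    lr_decay_patience: int = 5
    beta_fallback: float = 1.0
    position_init_noise: float | None = 0.1  # retinotopic init jitter; None = random

    def __post_init__(self):
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.pretrain_epochs < 0:
            raise ValueError("pretrain_epochs must be >= 0")
        if self.pretrain_epochs > self.total_epochs:
            raise ValueError("pretrain_epochs cannot exceed total_epochs")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not self.dof > 2:
            raise ValueError(f"dof must exceed 2 (got {self.dof})")
        if self.clamp_floor <= 0:
            raise ValueError("clamp_floor must be positive")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DECState:
    """Cluster centers of the unit-scale DEC ablation (kernel dof nu)."""

    centers: NDArray[np.float64]
    dof: float = 1.0


@dataclass
class TrainResult:
    model: object
    state: object  # TMixtureState or DECState
    history: list[dict]
    labels: NDArray[np.int64] | None
    beta: float | None
    seed: int

    def final(self, key: str):
        return self.history[-1][key] if self.history else None


class _Adam:
    """Adam over a dict of named parameter arrays; updates in place."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mh = self.m[k] / (1 - b1**self.t)
            vh = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# model plumbing


def build_model(dataset: StimulusResponseDataset, config: TrainConfig):
    """Seeded model initialization from the 'model-init' stream.

    For the core-readout model, readout positions start from a retinotopic
    estimate when the dataset provides receptive-field positions (real
    pipelines obtain these from a separate RF-mapping stimulus): the stored
    positions jittered by ``position_init_noise``. Positions remain learnable
    either way.
    """
    rng = seed_stream(config.seed, "model-init")
    if config.model_kind == "linear-toy":
        return LinearNeuronModel.init(
            dataset.n_neurons, dataset.stimuli.shape[1], rng
        )
    model = CoreReadoutModel.init(
        dataset.n_neurons,
        config.embedding_dim,
        rng,
        in_channels=dataset.stimuli.shape[-1],
    )
    if dataset.true_positions is not None and config.position_init_noise is not None:
        jitter = rng.normal(
            scale=config.position_init_noise, size=dataset.true_positions.shape
        )
        model.params["positions"] = np.clip(
            dataset.true_positions + jitter, -1.0, 1.0
        )
    return model


def _param_dict(model) -> dict:
    if isinstance(model, LinearNeuronModel):
        return {"weights": model.weights}
    return model.params


def _model_loss_grads(model, X, Y, config: TrainConfig):
    """(loss, grads) of the predictive loss on one batch."""
    if isinstance(model, LinearNeuronModel):
        loss = mse_loss(model.predict(X), Y)
        return loss, {"weights": model.mse_grad(X, Y)}
    rates, cache = model.forward(X)
    loss = poisson_loss(rates, Y)
    grads = model.backward(cache, poisson_loss_grad(rates, Y))
    wd = config.weight_decay
    if wd:
        w = model.params["weights"]
        loss += wd * float(np.sum(w**2))
        grads["weights"] = grads["weights"] + 2.0 * wd * w
    return loss, grads


def _model_loss(model, X, Y, config: TrainConfig) -> float:
    if isinstance(model, LinearNeuronModel):
        return mse_loss(model.predict(X), Y)
    return poisson_loss(model.predict(X), Y)


def _val_metric(model, val: StimulusResponseDataset, config: TrainConfig) -> float:
    """Validation metric: MSE for linear neurons, mean per-neuron Pearson
    correlation for the Poisson model."""
    pred = model.predict(val.stimuli)
    if isinstance(model, LinearNeuronModel):
        return mse_loss(pred, val.responses)
    from .evaluation import mean_neuron_correlation

    return mean_neuron_correlation(pred, val.responses)


def _check_finite(loss: float, epoch: int, lr: float) -> None:
    if not math.isfinite(loss):
        raise DivergenceError(
            f"non-finite loss {loss!r} at epoch {epoch} (learning rate {lr})"
        )


def _batches(n: int, batch_size: int, seed: int, epoch: int):
    perm = seed_stream(seed, f"batch-epoch-{epoch}").permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start : start + batch_size]


class _Plateau:
    """Plateau learning-rate decay and early stopping on a loss to minimize."""

    def __init__(self, opt: _Adam, config: TrainConfig):
        self.opt = opt
        self.factor = config.lr_decay_factor
        self.patience = config.lr_decay_patience
        self.stop_patience = config.early_stop_patience
        self.best = np.inf
        self.bad = 0

    def update(self, value: float) -> bool:
        """Record an epoch value; returns True if training should stop."""
        if value < self.best - 1e-12:
            self.best = value
            self.bad = 0
            return False
        self.bad += 1
        if self.bad % self.patience == 0:
            self.opt.lr *= self.factor
        return self.stop_patience is not None and self.bad >= self.stop_patience


# ---------------------------------------------------------------------------
# pretraining


def pretrain(
    model,
    dataset: StimulusResponseDataset,
    config: TrainConfig,
    *,
    n_epochs: int | None = None,
    epoch_offset: int = 0,
    history: list[dict] | None = None,
):
    """Train the predictive model on its own loss for ``pretrain_epochs``.

    Returns the model (modified in place). With ``pretrain_epochs == 0`` the
    parameters are untouched. Reproducible: batch order comes from per-epoch
    named streams of the config seed.
    """
    n_epochs = config.pretrain_epochs if n_epochs is None else n_epochs
    if n_epochs == 0:
        return model
    train, val = dataset.split(config.val_fraction)
    opt = _Adam(_param_dict(model), config.learning_rate)
    sched = _Plateau(opt, config)
    for epoch in range(epoch_offset, epoch_offset + n_epochs):
        losses = []
        for idx in _batches(train.n_trials, config.batch_size, config.seed, epoch):
            loss, grads = _model_loss_grads(
                model, train.stimuli[idx], train.responses[idx], config
            )
            _check_finite(loss, epoch, opt.lr)
            opt.step(grads)
            if isinstance(model, CoreReadoutModel):
                model.clip_positions()
            losses.append(loss)
        val_loss = _model_loss(model, val.stimuli, val.responses, config)
        if history is not None:
            history.append(
                {
                    "epoch": epoch,
                    "model_loss": float(np.mean(losses)),
                    "clustering_loss": 0.0,
                    "total_loss": float(np.mean(losses)),
                    "val_metric": _val_metric(model, val, config),
                    "lr": opt.lr,
                }
            )
        if sched.update(val_loss):
            break
    return model


# ---------------------------------------------------------------------------
# clustering gradients


def _tmm_embedding_grad(Z, state: TMixtureState, Q, U, P):
    """dL_cluster/dZ for the t-mixture soft assignments, P constant."""
    diff = Z[:, None, :] - state.centers[None, :, :]
    coeff = (P - Q) * U  # (N, J)
    return np.einsum("nj,njk->nk", coeff, diff / state.scale_diags[None, :, :])


def _dec_soft_assign(Z, centers, dof: float = 1.0):
    """Unit-scale t-kernel soft assignments (vanilla DEC) and distances."""
    d2 = np.sum((Z[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
    logf = -0.5 * (dof + 1.0) * np.log1p(d2 / dof)
    logq = logf - np.logaddexp.reduce(logf, axis=1, keepdims=True)
    return np.exp(logq), d2


def _dec_embedding_grad(Z, centers, Q, P, d2, dof: float = 1.0):
    diff = Z[:, None, :] - centers[None, :, :]
    coeff = (P - Q) * (dof + 1.0) / (dof + d2)
    return np.einsum("nj,njk->nk", coeff, diff)


# ---------------------------------------------------------------------------
# beta heuristic


def beta_heuristic(
    model,
    dataset: StimulusResponseDataset,
    config: TrainConfig,
    state: TMixtureState,
) -> float:
    """Order-of-magnitude clustering weight at clustering start.

    Returns ``10 ** round(log10(L_model / L_cluster))`` so the weighted
    clustering loss matches the model loss's order of magnitude. Falls back
    to ``config.beta_fallback`` (with a warning) if the clustering loss is
    zero at start.
    """
    train, _ = dataset.split(config.val_fraction)
    l_model = _model_loss(model, train.stimuli, train.responses, config)
    Q, _ = e_step(model.embeddings, state)
    P, _ = target_distribution(Q)
    l_cluster = clustering_loss(Q, P)
    if l_cluster == 0:
        warnings.warn(
            "clustering loss is zero at initialization; using fallback beta",
            RuntimeWarning,
        )
        return config.beta_fallback
    if l_model == 0 or not math.isfinite(l_cluster):
        warnings.warn(
            "degenerate loss ratio at initialization; using fallback beta",
            RuntimeWarning,
        )
        return config.beta_fallback
    # magnitudes only: the Poisson loss r_hat - r log r_hat can be negative
    return float(10.0 ** round(math.log10(abs(l_model) / l_cluster)))


# ---------------------------------------------------------------------------
# the DECEMber loop


def decembr_fit(
    model,
    dataset: StimulusResponseDataset,
    config: TrainConfig,
    *,
    on_batch: Callable[[dict], None] | None = None,
) -> TrainResult:
    """Algorithm: interleaved E-step / M-step / gradient-step training.

    The model is assumed pretrained (``pretrain_epochs`` may be 0 to skip
    that assumption explicitly). Each minibatch runs the E- and M-steps over
    all N embeddings and then takes one gradient step on
    ``model_loss_weight * L_model(batch) + beta * L_cluster``, where the
    clustering loss and its embedding gradient are evaluated under the
    mixture state produced by that batch's M-step and the target P is a
    constant. With ``beta == 0`` the clustering machinery is inert and the
    parameter trajectory is identical to continued pretraining.
    """
    Z = model.embeddings
    if Z.shape[0] < config.num_clusters:
        raise ValueError("need at least num_clusters embeddings")
    train, val = dataset.split(config.val_fraction)
    init_seed = int(seed_stream(config.seed, "kmeans-init").integers(2**31))
    state = init_clusters(
        Z,
        config.num_clusters,
        seed=init_seed,
        dof=config.dof,
        clamp_floor=config.clamp_floor,
    )
    beta = config.beta
    if beta is None:
        beta = beta_heuristic(model, dataset, config, state)

    opt = _Adam(_param_dict(model), config.learning_rate)
    sched = _Plateau(opt, config)
    history: list[dict] = []
    n_epochs = config.total_epochs - config.pretrain_epochs
    Q = P = None
    for epoch in range(config.pretrain_epochs, config.pretrain_epochs + n_epochs):
        model_losses, cluster_losses = [], []
        for b, idx in enumerate(
            _batches(train.n_trials, config.batch_size, config.seed, epoch)
        ):
            Z = model.embeddings
            if beta > 0:
                Q, U = e_step(Z, state)
                state, reseeded = reseed_empty_clusters(Z, Q, state)
                if reseeded:
                    Q, U = e_step(Z, state)
                state = m_step(Z, Q, U, state)
                # loss and gradient use the state this M-step just produced
                Q, U = e_step(Z, state)
                P, _ = target_distribution(Q)
                l_cluster = clustering_loss(Q, P)
                grad_Z_cluster = _tmm_embedding_grad(Z, state, Q, U, P)
            else:
                l_cluster = 0.0
                grad_Z_cluster = None

            if config.model_loss_weight > 0:
                l_model, grads = _model_loss_grads(
                    model, train.stimuli[idx], train.responses[idx], config
                )
                if config.model_loss_weight != 1.0:
                    l_model_w = config.model_loss_weight * l_model
                    grads = {
                        k: config.model_loss_weight * g for k, g in grads.items()
                    }
                else:
                    l_model_w = l_model
            else:
                l_model = l_model_w = 0.0
                grads = {k: np.zeros_like(v) for k, v in _param_dict(model).items()}
            if grad_Z_cluster is not None:
                grads["weights"] = grads["weights"] + beta * grad_Z_cluster
            total = l_model_w + beta * l_cluster
            _check_finite(total, epoch, opt.lr)
            if on_batch is not None:
                on_batch(
                    {
                        "epoch": epoch,
                        "batch": b,
                        "state_after_m_step": state,
                        "state_used_for_grad": state,
                        "Q": Q,
                        "P": P,
                        "clustering_loss": l_cluster,
                    }
                )
            opt.step(grads)
            if isinstance(model, CoreReadoutModel):
                model.clip_positions()
            model_losses.append(l_model)
            cluster_losses.append(l_cluster)
        val_loss = _model_loss(model, val.stimuli, val.responses, config)
        history.append(
            {
                "epoch": epoch,
                "model_loss": float(np.mean(model_losses)),
                "clustering_loss": float(np.mean(cluster_losses)),
                "total_loss": float(
                    config.model_loss_weight * np.mean(model_losses)
                    + beta * np.mean(cluster_losses)
                ),
                "val_metric": _val_metric(model, val, config),
                "lr": opt.lr,
            }
        )
        stop_value = val_loss if config.model_loss_weight > 0 else float(
            np.mean(cluster_losses)
        )
        if sched.update(stop_value):
            break

    labels = None
    if beta > 0 or config.num_clusters <= model.embeddings.shape[0]:
        Qf, _ = e_step(model.embeddings, state)
        labels = map_assign(Qf)
    return TrainResult(
        model=model,
        state=state,
        history=history,
        labels=labels,
        beta=beta,
        seed=config.seed,
    )


def dec_unit_scale_fit(
    model,
    dataset: StimulusResponseDataset,
    config: TrainConfig,
    *,
    kernel_dof: float = 1.0,
    on_batch: Callable[[dict], None] | None = None,
) -> TrainResult:
    """Vanilla-DEC ablation: unit-scale kernel, no scale adaptation.

    Soft assignments come from the fixed unit-scale t-kernel with
    ``kernel_dof`` (1 in vanilla DEC); centers are updated each batch as the
    plain responsibility-weighted mean of all embeddings (the center update
    of the EM machinery with latent scales frozen at 1), and the scale
    matrices are never adapted. Embeddings receive gradient steps on the same
    KL loss. Used to reproduce the center-collapse failure mode.
    """
    Z = model.embeddings
    train, val = dataset.split(config.val_fraction)
    init_seed = int(seed_stream(config.seed, "kmeans-init").integers(2**31))
    from sklearn.cluster import KMeans

    km = KMeans(
        n_clusters=config.num_clusters, n_init=10, random_state=init_seed % (2**31)
    ).fit(Z)
    centers = km.cluster_centers_.astype(np.float64)
    beta = config.beta if config.beta is not None else 1.0

    opt = _Adam(_param_dict(model), config.learning_rate)
    history: list[dict] = []
    n_epochs = config.total_epochs - config.pretrain_epochs
    for epoch in range(config.pretrain_epochs, config.pretrain_epochs + n_epochs):
        model_losses, cluster_losses = [], []
        for idx in _batches(train.n_trials, config.batch_size, config.seed, epoch):
            Z = model.embeddings
            if beta > 0:
                Q, _ = _dec_soft_assign(Z, centers, kernel_dof)
                centers = (Q.T @ Z) / Q.sum(axis=0)[:, None]
                Q, d2 = _dec_soft_assign(Z, centers, kernel_dof)
                P, _ = target_distribution(Q)
                l_cluster = clustering_loss(Q, P)
                grad_Z_cluster = _dec_embedding_grad(Z, centers, Q, P, d2, kernel_dof)
            else:
                l_cluster = 0.0
                grad_Z_cluster = None
            if config.model_loss_weight > 0:
                l_model, grads = _model_loss_grads(
                    model, train.stimuli[idx], train.responses[idx], config
                )
            else:
                l_model = 0.0
                grads = {k: np.zeros_like(v) for k, v in _param_dict(model).items()}
            if grad_Z_cluster is not None:
                grads["weights"] = grads["weights"] + beta * grad_Z_cluster
            total = config.model_loss_weight * l_model + beta * l_cluster
            _check_finite(total, epoch, opt.lr)
            if on_batch is not None:
                on_batch(
                    {
                        "epoch": epoch,
                        "centers": centers.copy(),
                        "clustering_loss": l_cluster,
                    }
                )
            opt.step(grads)
            model_losses.append(l_model)
            cluster_losses.append(l_cluster)
        history.append(
            {
                "epoch": epoch,
                "model_loss": float(np.mean(model_losses)),
                "clustering_loss": float(np.mean(cluster_losses)),
                "total_loss": float(
                    config.model_loss_weight * np.mean(model_losses)
                    + beta * np.mean(cluster_losses)
                ),
                "val_metric": _val_metric(model, val, config),
                "lr": opt.lr,
            }
        )
    Qf, _ = _dec_soft_assign(model.embeddings, centers, kernel_dof)
    return TrainResult(
        model=model,
        state=DECState(centers=centers, dof=kernel_dof),
        history=history,
        labels=map_assign(Qf),
        beta=beta,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# sklearn-style front end


from sklearn.base import BaseEstimator


class DECEMber(BaseEstimator):
    """Estimator wrapping the full pipeline: pretrain, init, joint loop.

    ``fit`` takes a :class:`StimulusResponseDataset`; fitted attributes are
    ``model_`` (the trained predictive model), ``state_`` (the t-mixture
    state), ``labels_`` (MAP cluster labels per neuron), ``history_`` and
    ``beta_``. ``variant='dec-unit-scale'`` runs the vanilla-DEC ablation.
    """

    def __init__(
        self,
        beta: float | None = None,
        pretrain_epochs: int = 25,
        total_epochs: int = 50,
        learning_rate: float = 0.01,
        batch_size: int = 256,
        num_clusters: int = 2,
        dof: float = 2.1,
        clamp_floor: float = 1e-6,
        seed: int = 0,
        model_kind: str = "linear-toy",
        model_loss_weight: float = 1.0,
        embedding_dim: int = 8,
        variant: str = "december",
    ):
        self.beta = beta
        self.pretrain_epochs = pretrain_epochs
        self.total_epochs = total_epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.num_clusters = num_clusters
        self.dof = dof
        self.clamp_floor = clamp_floor
        self.seed = seed
        self.model_kind = model_kind
        self.model_loss_weight = model_loss_weight
        self.embedding_dim = embedding_dim
        self.variant = variant

    def _config(self) -> TrainConfig:
        return TrainConfig(
            beta=self.beta,
            pretrain_epochs=self.pretrain_epochs,
            total_epochs=self.total_epochs,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            num_clusters=self.num_clusters,
            dof=self.dof,
            clamp_floor=self.clamp_floor,
            seed=self.seed,
            model_kind=self.model_kind,
            model_loss_weight=self.model_loss_weight,
            embedding_dim=self.embedding_dim,
        )

    def fit(self, dataset: StimulusResponseDataset, y=None) -> "DECEMber":
        if self.variant not in ("december", "dec-unit-scale"):
            raise ValueError("variant must be 'december' or 'dec-unit-scale'")
        config = self._config()
        model = build_model(dataset, config)
        pretrain(model, dataset, config)
        fit_fn = (
            decembr_fit if self.variant == "december" else dec_unit_scale_fit
        )
        result = fit_fn(model, dataset, config)
        self.model_ = result.model
        self.state_ = result.state
        self.labels_ = result.labels
        self.history_ = result.history
        self.beta_ = result.beta
        self.result_ = result
        return self

    def predict(self, dataset: StimulusResponseDataset) -> NDArray[np.float64]:
        """Predicted responses for new stimuli."""
        return self.model_.predict(dataset.stimuli)
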