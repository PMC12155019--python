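"""Predictive models whose per-neuron weights are the functional embeddings.

Two model families are provided:

* :class:`LinearNeuronModel` — linear neurons ``y_i = z_i^T x`` used by the
  toy clustering experiments; the weight matrix Z is the embedding matrix.
* :class:`CoreReadoutModel` — a miniature core–readout model: a small shared
  convolutional core produces an H x W x K feature map, and each neuron's
  Gaussian readout bilinearly interpolates the map at its receptive-field
  position (x_i, y_i) and takes the dot product with its weight vector z_i,
  followed by a softplus to yield a strictly positive firing rate.

Both are plain NumPy models with analytically derived gradients (checked
against finite differences in the test suite), so training is deterministic
and dependency-light.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
from numpy.typing import ArrayLike, NDArray

logger = logging.getLogger(__name__)

__all__ = [
    "LinearNeuronModel",
    "CoreReadoutModel",
    "linear_predict",
    "readout_predict",
    "poisson_loss",
    "mse_loss",
    "core_forward",
    "bilinear_interpolate",
]

_RATE_EPS = 1e-6  # shift keeping softplus rates strictly positive


# ---------------------------------------------------------------------------
# losses


def mse_loss(predicted: ArrayLike, observed: ArrayLike) -> float:
    """Mean squared error over all entries."""
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {observed.shape}")
    return float(np.mean((predicted - observed) ** 2))


def poisson_loss(predicted: ArrayLike, observed: ArrayLike) -> float:
    """Poisson loss (1/N) sum_l sum_i (rhat_li - r_li log rhat_li).

    Normalized by the number of neurons N only, not by the number of images,
    so the loss scales with dataset size.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {observed.shape}")
    if np.any(predicted <= 0):
        raise ValueError("predicted rates must be strictly positive")
    n_neurons = predicted.shape[1]
    return float(np.sum(predicted - observed * np.log(predicted)) / n_neurons)


def poisson_loss_grad(
    predicted: NDArray[np.float64], observed: NDArray[np.float64]
) -> NDArray[np.float64]:
    return (1.0 - observed / predicted) / predicted.shape[1]


# ---------------------------------------------------------------------------
# linear toy model


class LinearNeuronModel:
    """Population of linear neurons with responses y_i = z_i^T x.

    The only parameters are the N x K weight matrix ``weights`` — the
    functional embeddings themselves.
    """

    def __init__(self, weights: ArrayLike):
        self.weights = np.asarray(weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValueError("weights must be an N x K matrix")

    @classmethod
    def init(cls, n_neurons: int, n_features: int, rng: np.random.Generator):
        w = rng.normal(scale=0.01, size=(n_neurons, n_features))
        return cls(w)

    @property
    def embeddings(self) -> NDArray[np.float64]:
        return self.weights

    def predict(self, stimuli: ArrayLike) -> NDArray[np.float64]:
        return linear_predict(self, stimuli)

    def mse_grad(
        self, stimuli: NDArray[np.float64], responses: NDArray[np.float64]
    ) -> NDArray[np.float64]:
        """d(MSE)/dZ for predictions X Z^T against ``responses``."""
        pred = self.predict(stimuli)
        resid = pred - responses  # (B, N)
        return 2.0 * resid.T @ stimuli / resid.size

    def copy(self) -> "LinearNeuronModel":
        return LinearNeuronModel(self.weights.copy())


def linear_predict(model: LinearNeuronModel, stimuli: ArrayLike) -> NDArray[np.float64]:
    """Responses of linear neurons: output[b, i] = <z_i, x_b>."""
    X = np.asarray(stimuli, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.weights.shape[1]:
        raise ValueError(
            f"stimuli shape {X.shape} incompatible with weights "
            f"{model.weights.shape}"
        )
    return X @ model.weights.T


# ---------------------------------------------------------------------------
# convolution primitives (stride 1, zero 'same' padding)


def _conv2d_forward(x, w, b):
    """x: (B, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,)."""
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    patches = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # patches: (B, H, W, Cin, kh, kw)
    out = np.einsum("bhwckl,klcd->bhwd", patches, w, optimize=True) + b
    return out, patches


def _conv2d_backward(patches, w, dy):
    """Gradients of a same-padded stride-1 conv. Returns (dx, dw, db)."""
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    dw = np.einsum("bhwckl,bhwd->klcd", patches, dy, optimize=True)
    db = dy.sum(axis=(0, 1, 2))
    # dx: correlate dy with the kernel flipped in space, swapped channels
    w_flip = w[::-1, ::-1]  # (kh, kw, Cin, Cout)
    dyp = np.pad(dy, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    dpatches = np.lib.stride_tricks.sliding_window_view(dyp, (kh, kw), axis=(1, 2))
    # (B, H, W, Cout, kh, kw) x (kh, kw, Cin, Cout) -> (B, H, W, Cin)
    dx = np.einsum("bhwdkl,klcd->bhwc", dpatches, w_flip, optimize=True)
    return dx, dw, db


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_grad(x):
    # sigmoid, computed stably
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------
# bilinear readout


def bilinear_interpolate(
    feature_map: NDArray[np.float64], positions: NDArray[np.float64]
):
    """Bilinearly interpolate an (H, W, K) map at normalized positions.

    Positions live in [-1, 1]^2 with (x, y) = (-1, -1) mapping to grid node
    (row 0, col 0) and (1, 1) to (H-1, W-1); x indexes columns, y rows. At
    exact grid nodes the interpolation returns the node value.

    Returns the (M, K) feature vectors plus the cache needed for gradients.
    """
    H, W, _ = feature_map.shape
    pos = np.asarray(positions, dtype=np.float64)
    gx = (pos[:, 0] + 1.0) / 2.0 * (W - 1)  # column coordinate
    gy = (pos[:, 1] + 1.0) / 2.0 * (H - 1)  # row coordinate
    x0 = np.clip(np.floor(gx).astype(int), 0, W - 2) if W > 1 else np.zeros_like(gx, int)
    y0 = np.clip(np.floor(gy).astype(int), 0, H - 2) if H > 1 else np.zeros_like(gy, int)
    tx = gx - x0
    ty = gy - y0
    f00 = feature_map[y0, x0]
    f01 = feature_map[y0, x0 + 1] if W > 1 else f00
    f10 = feature_map[y0 + 1, x0] if H > 1 else f00
    f11 = feature_map[y0 + 1, x0 + 1] if (H > 1 and W > 1) else f00
    tx_ = tx[:, None]
    ty_ = ty[:, None]
    phi = (
        (1 - ty_) * (1 - tx_) * f00
        + (1 - ty_) * tx_ * f01
        + ty_ * (1 - tx_) * f10
        + ty_ * tx_ * f11
    )
    cache = (x0, y0, tx, ty, f00, f01, f10, f11, H, W)
    return phi, cache


def readout_predict(
    feature_map: ArrayLike, position: ArrayLike, weight: ArrayLike
) -> float:
    """Single-neuron Gaussian-readout prediction from one feature map.

    Interpolates the H x W x K map at the neuron's receptive-field position,
    dots with the weight vector and maps through the softplus output
    nonlinearity to a strictly positive rate. Positions outside [-1, 1]^2
    are clipped (logged at debug level).
    """
    fm = np.asarray(feature_map, dtype=np.float64)
    pos = np.asarray(position, dtype=np.float64).reshape(1, 2)
    if np.any(np.abs(pos) > 1.0):
        logger.debug("readout position %s outside [-1, 1]^2; clipping", pos)
        pos = np.clip(pos, -1.0, 1.0)
    w = np.asarray(weight, dtype=np.float64)
    phi, _ = bilinear_interpolate(fm, pos)
    return float(_softplus(phi[0] @ w) + _RATE_EPS)


# ---------------------------------------------------------------------------
# miniature core-readout model


class CoreReadoutModel:
    """Miniature core–readout Poisson rate model.

    Architecture: two same-padded 5x5 convolutions (C -> ``hidden_channels``
    -> K feature channels) with ELU nonlinearities form the shared core; each
    neuron reads the feature map at its learned position via bilinear
    interpolation, applies its K-vector of readout weights plus a per-neuron
    bias, and a softplus yields the positive predicted rate.

    Parameters are held in ``params`` (a dict of ndarrays) so the trainer can
    treat them uniformly. Readout positions are clipped back into [-1, 1]^2
    after every update.
    """

    PARAM_KEYS = (
        "conv1_w",
        "conv1_b",
        "conv2_w",
        "conv2_b",
        "positions",
        "weights",
        "bias",
    )

    def __init__(self, params: Mapping[str, NDArray[np.float64]]):
        self.params = {k: np.asarray(v, dtype=np.float64) for k, v in params.items()}
        missing = set(self.PARAM_KEYS) - set(self.params)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")

    @classmethod
    def init(
        cls,
        n_neurons: int,
        n_features: int,
        rng: np.random.Generator,
        *,
        in_channels: int = 1,
        hidden_channels: int = 9,
        kernel_size: int = 5,
    ) -> "CoreReadoutModel":
        k = kernel_size
        def he(shape, fan_in):
            return rng.normal(scale=np.sqrt(2.0 / fan_in), size=shape)

        params = {
            "conv1_w": he((k, k, in_channels, hidden_channels), k * k * in_channels),
            "conv1_b": np.zeros(hidden_channels),
            "conv2_w": he((k, k, hidden_channels, n_features), k * k * hidden_channels),
            "conv2_b": np.zeros(n_features),
            "positions": rng.uniform(-0.8, 0.8, size=(n_neurons, 2)),
            "weights": rng.normal(scale=0.1, size=(n_neurons, n_features)),
            "bias": np.zeros(n_neurons),
        }
        return cls(params)

    @property
    def embeddings(self) -> NDArray[np.float64]:
        """The N x K readout-weight matrix — the functional embeddings."""
        return self.params["weights"]

    @property
    def n_neurons(self) -> int:
        return self.params["weights"].shape[0]

    def copy(self) -> "CoreReadoutModel":
        return CoreReadoutModel({k: v.copy() for k, v in self.params.items()})

    # -- forward ------------------------------------------------------------

    def core_features(self, stimuli: ArrayLike) -> NDArray[np.float64]:
        out, _ = self._core_forward_cached(np.asarray(stimuli, dtype=np.float64))
        return out

    def _core_forward_cached(self, x):
        p = self.params
        a1, patches1 = _conv2d_forward(x, p["conv1_w"], p["conv1_b"])
        h1 = _elu(a1)
        a2, patches2 = _conv2d_forward(h1, p["conv2_w"], p["conv2_b"])
        fmap = _elu(a2)
        cache = (x, a1, patches1, h1, a2, patches2)
        return fmap, cache

    def forward(self, stimuli: ArrayLike):
        """Predicted rates (B, N) plus the cache for :meth:`backward`.

        The readout is vectorized over the batch: every neuron's position is
        shared across images, so the four interpolation corners are gathered
        once per neuron.
        """
        x = np.asarray(stimuli, dtype=np.float64)
        fmap, core_cache = self._core_forward_cached(x)
        B, H, W, K = fmap.shape
        p = self.params
        pos = np.clip(p["positions"], -1.0, 1.0)
        gx = (pos[:, 0] + 1.0) / 2.0 * (W - 1)
        gy = (pos[:, 1] + 1.0) / 2.0 * (H - 1)
        x0 = np.clip(np.floor(gx).astype(int), 0, max(W - 2, 0))
        y0 = np.clip(np.floor(gy).astype(int), 0, max(H - 2, 0))
        x1 = np.minimum(x0 + 1, W - 1)
        y1 = np.minimum(y0 + 1, H - 1)
        tx = (gx - x0)[None, :, None]  # (1, N, 1)
        ty = (gy - y0)[None, :, None]
        f00 = fmap[:, y0, x0]  # (B, N, K)
        f01 = fmap[:, y0, x1]
        f10 = fmap[:, y1, x0]
        f11 = fmap[:, y1, x1]
        phis = (
            (1 - ty) * (1 - tx) * f00
            + (1 - ty) * tx * f01
            + ty * (1 - tx) * f10
            + ty * tx * f11
        )
        pre = np.einsum("bnk,nk->bn", phis, p["weights"]) + p["bias"]
        rates = _softplus(pre) + _RATE_EPS
        interp = (x0, y0, x1, y1, tx, ty, f00, f01, f10, f11)
        cache = (core_cache, fmap, phis, interp, pre, pos)
        return rates, cache

    def predict(self, stimuli: ArrayLike) -> NDArray[np.float64]:
        rates, _ = self.forward(stimuli)
        return rates

    # -- backward -----------------------------------------------------------

    def backward(self, cache, d_rates: NDArray[np.float64]):
        """Gradients of a scalar loss given d(loss)/d(rates)."""
        core_cache, fmap, phis, interp, pre, pos = cache
        x, a1, patches1, h1, a2, patches2 = core_cache
        p = self.params
        B, H, W, K = fmap.shape
        x0, y0, x1, y1, tx, ty, f00, f01, f10, f11 = interp

        d_pre = d_rates * _softplus_grad(pre)  # (B, N)
        d_weights = np.einsum("bn,bnk->nk", d_pre, phis)
        d_bias = d_pre.sum(axis=0)
        d_phis = d_pre[:, :, None] * p["weights"][None, :, :]  # (B, N, K)

        d_fmap = np.zeros_like(fmap)
        bidx = np.arange(B)[:, None]
        np.add.at(d_fmap, (bidx, y0[None, :], x0[None, :]), (1 - ty) * (1 - tx) * d_phis)
        np.add.at(d_fmap, (bidx, y0[None, :], x1[None, :]), (1 - ty) * tx * d_phis)
        np.add.at(d_fmap, (bidx, y1[None, :], x0[None, :]), ty * (1 - tx) * d_phis)
        np.add.at(d_fmap, (bidx, y1[None, :], x1[None, :]), ty * tx * d_phis)
        # d phi / d tx = (1-ty)(f01-f00) + ty(f11-f10); chain to x by grid scale
        dtx = np.sum(d_phis * ((1 - ty) * (f01 - f00) + ty * (f11 - f10)), axis=(0, 2))
        dty = np.sum(d_phis * ((1 - tx) * (f10 - f00) + tx * (f11 - f01)), axis=(0, 2))
        d_pos = np.stack([dtx * (W - 1) / 2.0, dty * (H - 1) / 2.0], axis=1)

        d_a2 = d_fmap * _elu_grad(a2)
        d_h1, d_conv2_w, d_conv2_b = _conv2d_backward(patches2, p["conv2_w"], d_a2)
        d_a1 = d_h1 * _elu_grad(a1)
        _, d_conv1_w, d_conv1_b = _conv2d_backward(patches1, p["conv1_w"], d_a1)

        return {
            "conv1_w": d_conv1_w,
            "conv1_b": d_conv1_b,
            "conv2_w": d_conv2_w,
            "conv2_b": d_conv2_b,
            "positions": d_pos,
            "weights": d_weights,
            "bias": d_bias,
        }

    def clip_positions(self) -> None:
        np.clip(self.params["positions"], -1.0, 1.0, out=self.params["positions"])


def core_forward(model: CoreReadoutModel, stimuli: ArrayLike) -> NDArray[np.float64]:
    """Shared-core feature maps, shape (B, H, W, K)."""
    return model.core_features(stimuli)
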