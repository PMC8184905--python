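"""Minimal numpy neural-network primitives.

This module supplies the recurrent and convolutional building blocks used by
the feature extractors (LSTM, convolutional LSTM, a small convolutional image
backbone) and the trainable fusion head (linear -> batch-norm -> ReLU ->
dropout -> linear) with its Adam/mean-absolute-error training loop.  Every
function is a pure, seeded computation on float64 numpy arrays, so the whole
pipeline is bit-reproducible on one machine.

Convolutions are evaluated with zero padding ("same" output size) through
real FFTs, batched over records; for the kernel sizes used here this is far
cheaper than direct sliding-window products.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import fft as sfft

__all__ = [
    "glorot",
    "conv_same",
    "init_lstm",
    "lstm_forward",
    "init_convlstm",
    "convlstm_forward",
    "init_stub_cnn",
    "stub_cnn_forward",
    "init_linear",
    "linear_forward",
    "FusionHead",
    "params_checksum",
]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------
# batched "same" convolution via FFT
# ---------------------------------------------------------------------------

def conv_same(x: np.ndarray, k: np.ndarray, chunk: int = 32) -> np.ndarray:
    """Correlate a batch of multi-channel grids with a kernel bank.

    Parameters
    ----------
    x : array, shape (B, C_in, *spatial)
    k : array, shape (C_out, C_in, *kernel), every kernel dimension odd
    chunk : batch chunk size bounding FFT workspace memory.

    Returns array of shape (B, C_out, *spatial), zero-padded at the borders.
    """
    spatial = x.shape[2:]
    ksize = k.shape[2:]
    if len(spatial) != len(ksize):
        raise ValueError("kernel rank does not match input rank")
    if any(s % 2 == 0 for s in ksize):
        raise ValueError("kernel dimensions must be odd")
    full = tuple(s + t - 1 for s, t in zip(spatial, ksize))
    axes = tuple(range(2, 2 + len(spatial)))
    # correlation == convolution with a flipped kernel
    kf = sfft.rfftn(np.flip(k, axis=axes), s=full, axes=axes)
    out = np.empty((x.shape[0], k.shape[0]) + spatial, dtype=np.float64)
    lo = tuple(t // 2 for t in ksize)
    crop = tuple(slice(l, l + s) for l, s in zip(lo, spatial))
    for start in range(0, x.shape[0], chunk):
        xb = x[start : start + chunk]
        xf = sfft.rfftn(xb, s=full, axes=axes)
        yf = np.einsum("bi...,oi...->bo...", xf, kf)
        yb = sfft.irfftn(yf, s=full, axes=axes)
        out[start : start + chunk] = yb[(slice(None), slice(None)) + crop]
    return out


# ---------------------------------------------------------------------------
# LSTM on flat sequences
# ---------------------------------------------------------------------------

def init_lstm(rng: np.random.Generator, input_dim: int, hidden: int) -> dict:
    """LSTM parameters; gate order (i, f, g, o), forget bias 1."""
    p = {
        "Wx": glorot(rng, (input_dim, 4 * hidden), input_dim, hidden),
        "Wh": glorot(rng, (hidden, 4 * hidden), hidden, hidden),
        "b": np.zeros(4 * hidden),
    }
    p["b"][hidden : 2 * hidden] = 1.0
    return p


def lstm_forward(x: np.ndarray, params: dict) -> np.ndarray:
    """Run an LSTM over x (B, T, D); return the final hidden state (B, H)."""
    hdim = params["Wh"].shape[0]
    B = x.shape[0]
    h = np.zeros((B, hdim))
    c = np.zeros((B, hdim))
    for t in range(x.shape[1]):
        gates = x[:, t] @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = _sigmoid(gates[:, :hdim])
        f = _sigmoid(gates[:, hdim : 2 * hdim])
        g = np.tanh(gates[:, 2 * hdim : 3 * hdim])
        o = _sigmoid(gates[:, 3 * hdim :])
        c = f * c + i * g
        h = o * np.tanh(c)
    return h


# ---------------------------------------------------------------------------
# convolutional LSTM on grid sequences
# ---------------------------------------------------------------------------

def init_convlstm(
    rng: np.random.Generator, in_channels: int, filters: int, kernel: tuple[int, ...]
) -> dict:
    fan_k = int(np.prod(kernel))
    p = {
        "Wx": glorot(rng, (4 * filters, in_channels) + kernel, in_channels * fan_k, filters * fan_k),
        "Wh": glorot(rng, (4 * filters, filters) + kernel, filters * fan_k, filters * fan_k),
        "b": np.zeros(4 * filters),
    }
    p["b"][filters : 2 * filters] = 1.0
    return p


def convlstm_forward(x: np.ndarray, params: dict) -> np.ndarray:
    """Convolutional LSTM over x (B, T, C_in, *spatial).

    Gates are convolutions of the input and hidden grids; returns the final
    hidden state (B, F, *spatial).
    """
    filters = params["Wh"].shape[1]
    spatial = x.shape[3:]
    B = x.shape[0]
    h = np.zeros((B, filters) + spatial)
    c = np.zeros_like(h)
    bias = params["b"].reshape((1, 4 * filters) + (1,) * len(spatial))
    for t in range(x.shape[1]):
        gates = conv_same(x[:, t], params["Wx"]) + bias
        if t > 0:  # h is zero before the first step
            gates += conv_same(h, params["Wh"])
        i = _sigmoid(gates[:, :filters])
        f = _sigmoid(gates[:, filters : 2 * filters])
        g = np.tanh(gates[:, 2 * filters : 3 * filters])
        o = _sigmoid(gates[:, 3 * filters :])
        c = f * c + i * g
        h = o * np.tanh(c)
    return h


# ---------------------------------------------------------------------------
# stub 2D convolutional backbone
# ---------------------------------------------------------------------------

def init_stub_cnn(rng: np.random.Generator, in_channels: int = 3, width: int = 16) -> dict:
    """A small fixed-seed two-layer conv net standing in for a pre-trained
    2D backbone.  Its parameters are never trained."""
    c1 = max(width // 2, 4)
    return {
        "k1": glorot(rng, (c1, in_channels, 5, 5), in_channels * 25, c1 * 25),
        "b1": np.zeros(c1),
        "k2": glorot(rng, (width, c1, 5, 5), c1 * 25, width * 25),
        "b2": np.zeros(width),
    }


def stub_cnn_forward(x: np.ndarray, params: dict) -> np.ndarray:
    """Embed a batch of images (B, C, H, W) into (B, width) by two conv+ReLU
    layers with 2x decimation and a global average pool."""
    h = conv_same(x, params["k1"]) + params["b1"][None, :, None, None]
    h = np.maximum(h, 0.0)[:, :, ::2, ::2]
    h = conv_same(h, params["k2"]) + params["b2"][None, :, None, None]
    h = np.maximum(h, 0.0)[:, :, ::2, ::2]
    return h.mean(axis=(2, 3))


# ---------------------------------------------------------------------------
# linear projection
# ---------------------------------------------------------------------------

def init_linear(rng: np.random.Generator, d_in: int, d_out: int) -> dict:
    return {"W": glorot(rng, (d_in, d_out), d_in, d_out), "b": np.zeros(d_out)}


def linear_forward(x: np.ndarray, params: dict) -> np.ndarray:
    return x @ params["W"] + params["b"]


# ---------------------------------------------------------------------------
# trainable fusion head
# ---------------------------------------------------------------------------

class FusionHead:
    """Fully connected regression head: linear -> batch-norm -> ReLU ->
    dropout -> linear, trained with Adam on a mean-absolute-error loss.

    Batch normalization keeps running statistics (momentum 0.1); inference
    always uses them, so a prediction for one record does not depend on the
    rest of the batch.  Dropout (inverted scaling) is active only in
    training mode.
    """

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, input_dim: int, hidden: int, dropout_p: float, seed: int):
        if not 0.0 <= dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.hidden = hidden
        self.dropout_p = float(dropout_p)
        self.params = {
            "W1": glorot(rng, (input_dim, hidden), input_dim, hidden),
            "b1": np.zeros(hidden),
            "gamma": np.ones(hidden),
            "beta": np.zeros(hidden),
            "W2": glorot(rng, (hidden, 1), hidden, 1),
            "b2": np.zeros(1),
        }
        self.running_mean = np.zeros(hidden)
        self.running_var = np.ones(hidden)

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Predict (B,) from features (B, d).  Training mode uses batch
        statistics and dropout and caches intermediates for backward()."""
        if x.ndim != 2 or x.shape[1] != self.input_dim:
            raise ValueError(
                f"feature matrix has width {x.shape[-1] if x.ndim else '?'}, "
                f"expected {self.input_dim}"
            )
        p = self.params
        z1 = x @ p["W1"] + p["b1"]
        if training:
            mu = z1.mean(axis=0)
            var = z1.var(axis=0)
            self.running_mean = (1 - self.BN_MOMENTUM) * self.running_mean + self.BN_MOMENTUM * mu
            self.running_var = (1 - self.BN_MOMENTUM) * self.running_var + self.BN_MOMENTUM * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
        zhat = (z1 - mu) * inv_std
        a = p["gamma"] * zhat + p["beta"]
        r = np.maximum(a, 0.0)
        if training and self.dropout_p > 0.0:
            if rng is None:
                raise ValueError("training-mode forward with dropout needs an rng")
            mask = (rng.random(r.shape) >= self.dropout_p) / (1.0 - self.dropout_p)
        else:
            mask = np.ones_like(r)
        d = r * mask
        y = (d @ p["W2"] + p["b2"])[:, 0]
        if training:
            self._cache = (x, z1, mu, inv_std, zhat, a, r, mask, d)
        return y

    # -- backward ----------------------------------------------------------

    def _backward(self, dy: np.ndarray) -> dict:
        """Gradients of the scalar loss given dL/dy (B,), using the cache of
        the last training-mode forward.  Batch-norm backward uses the batch
        statistics of that forward."""
        x, z1, mu, inv_std, zhat, a, r, mask, d = self._cache
        p = self.params
        B = x.shape[0]
        g = {}
        g["W2"] = d.T @ dy[:, None]
        g["b2"] = np.array([dy.sum()])
        dd = dy[:, None] @ p["W2"].T
        dr = dd * mask
        da = dr * (a > 0)
        g["gamma"] = (da * zhat).sum(axis=0)
        g["beta"] = da.sum(axis=0)
        dzhat = da * p["gamma"]
        # batch-norm backward (over the batch dimension)
        dvar_term = (dzhat * zhat).sum(axis=0)
        dz1 = inv_std * (dzhat - dzhat.mean(axis=0) - zhat * dvar_term / B)
        g["W1"] = x.T @ dz1
        g["b1"] = dz1.sum(axis=0)
        return g

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        seed: int,
        callback: Callable[[int, float, float], None] | None = None,
    ) -> list[tuple[float, float]]:
        """Minimize MAE with Adam; returns per-epoch (train, validation) MAE
        measured in inference mode.  Raises on non-finite loss, naming the
        epoch and batch."""
        rng = np.random.default_rng(seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        history: list[tuple[float, float]] = []
        n = X.shape[0]
        for epoch in range(epochs):
            order = rng.permutation(n)
            for bidx, start in enumerate(range(0, n, batch_size)):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], y[idx]
                pred = self.forward(xb, training=True, rng=rng)
                resid = pred - yb
                loss = np.abs(resid).mean()
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch + 1}, batch {bidx + 1}"
                    )
                dy = np.sign(resid) / len(yb)
                grads = self._backward(dy)
                t += 1
                for k, gk in grads.items():
                    m[k] = beta1 * m[k] + (1 - beta1) * gk
                    v[k] = beta2 * v[k] + (1 - beta2) * gk * gk
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    self.params[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            tr = float(np.abs(self.forward(X) - y).mean())
            va = float(np.abs(self.forward(X_val) - y_val).mean())
            history.append((tr, va))
            if callback is not None:
                callback(epoch, tr, va)
        return history


def params_checksum(params: dict) -> str:
    """Order-independent hex digest of a parameter dict (used to assert that
    frozen parameters never change)."""
    import hashlib

    h = hashlib.sha256()
    for key in sorted(params):
        h.update(key.encode())
        h.update(np.ascontiguousarray(params[key], dtype=np.float64).tobytes())
    return h.hexdigest()
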