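"""Minimal convolutional building blocks with handwritten backprop.

Just enough machinery for the desk-scale image-to-mask translation
model: strided convolution, strided transposed convolution, leaky ReLU,
sigmoid, binary cross-entropy on logits, and Adam.  Arrays are NCHW
float64 throughout; im2col keeps everything as matrix products.

Gradient correctness is pinned by finite-difference tests rather than by
an autograd framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm",
    "Adam",
    "leaky_relu",
    "leaky_relu_grad",
    "sigmoid",
    "bce_with_logits",
    "bce_with_logits_grad",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return windows.reshape(n, c * k * k, ho * wo), (ho, wo)


def _col2im(
    cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int
) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for di in range(k):
        for dj in range(k):
            xp[:, :, di : di + stride * ho : stride, dj : dj + stride * wo : stride] += cols[
                :, :, di, dj
            ]
    return xp[:, :, pad : pad + h, pad : pad + w]


class _Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]


class Conv2d(_Layer):
    """k x k convolution (cross-correlation), weight shape (Cout, Cin, k, k)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 4,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        scale = 0.02  # DCGAN-style init
        self.k, self.stride, self.pad = k, stride, pad
        self.params = {
            "W": rng.normal(0.0, scale, (cout, cin, k, k)),
            "b": np.zeros(cout),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        w = self.params["W"]
        y = np.einsum("op,npq->noq", w.reshape(w.shape[0], -1), cols)
        y = y.reshape(x.shape[0], w.shape[0], ho, wo) + self.params["b"][None, :, None, None]
        self._cache = (x.shape, cols)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        w = self.params["W"]
        cout = w.shape[0]
        dyf = dy.reshape(dy.shape[0], cout, -1)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        self.grads["W"] += np.einsum("noq,npq->op", dyf, cols).reshape(w.shape)
        dcols = np.einsum("op,noq->npq", w.reshape(cout, -1), dyf)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(_Layer):
    """Strided transposed convolution, weight shape (Cin, Cout, k, k).

    Output size is (H-1)*stride - 2*pad + k; with k=4, stride=2, pad=1
    this exactly doubles the spatial size.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 4,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad = k, stride, pad
        self.params = {
            "W": rng.normal(0.0, 0.02, (cin, cout, k, k)),
            "b": np.zeros(cout),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def _out_shape(self, x: np.ndarray) -> tuple:
        n, cin, h, w = x.shape
        cout = self.params["W"].shape[1]
        ho = (h - 1) * self.stride - 2 * self.pad + self.k
        wo = (w - 1) * self.stride - 2 * self.pad + self.k
        return (n, cout, ho, wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.params["W"]
        cin = w.shape[0]
        out_shape = self._out_shape(x)
        xf = x.reshape(x.shape[0], cin, -1)
        cols = np.einsum("ip,niq->npq", w.reshape(cin, -1), xf)
        y = _col2im(cols, out_shape, self.k, self.stride, self.pad)
        self._cache = (x, out_shape)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, out_shape = self._cache
        w = self.params["W"]
        cin = w.shape[0]
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dycols, _ = _im2col(dy, self.k, self.stride, self.pad)
        xf = x.reshape(x.shape[0], cin, -1)
        self.grads["W"] += np.einsum("niq,npq->ip", xf, dycols).reshape(w.shape)
        dx = np.einsum("ip,npq->niq", w.reshape(cin, -1), dycols)
        return dx.reshape(x.shape)


class InstanceNorm(_Layer):
    """Per-sample, per-channel normalisation over H x W, with affine params.

    The batch-size-1 equivalent of the batch normalisation the original
    image-translation recipe relies on; without it the sigmoid output
    saturates against the class imbalance of sparse masks.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.params["gamma"][None, :, None, None] * xhat + self.params[
            "beta"
        ][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxhat = dy * g
        m = xhat.shape[2] * xhat.shape[3]
        return (
            inv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
            )
        )


def leaky_relu(x: np.ndarray, alpha: float = 0.2) -> np.ndarray:
    return np.where(x > 0, x, alpha * x)


def leaky_relu_grad(x: np.ndarray, alpha: float = 0.2) -> np.ndarray:
    return np.where(x > 0, 1.0, alpha)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, target: float) -> float:
    """Mean binary cross-entropy against a constant 0/1 target."""
    # log(1 + exp(-|z|)) + max(z, 0) - z*t, numerically stable
    loss = np.logaddexp(0.0, -np.abs(logits)) + np.maximum(logits, 0.0) - logits * target
    return float(loss.mean())


def bce_with_logits_grad(logits: np.ndarray, target: float) -> np.ndarray:
    return (sigmoid(logits) - target) / logits.size


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(
        self,
        layers: list[_Layer],
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.layers = [l for l in layers if getattr(l, "params", None)]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {n: np.zeros_like(p) for n, p in l.params.items()} for l in self.layers
        ]
        self.v = [
            {n: np.zeros_like(p) for n, p in l.params.items()} for l in self.layers
        ]

    def zero_grad(self) -> None:
        for l in self.layers:
            for g in l.grads.values():
                g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for n, p in l.params.items():
                g = l.grads[n]
                m[n] = self.b1 * m[n] + (1 - self.b1) * g
                v[n] = self.b2 * v[n] + (1 - self.b2) * g * g
                p -= self.lr * (m[n] / bc1) / (np.sqrt(v[n] / bc2) + self.eps)
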