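"""Minimal numpy neural-net kernels: conv/pool/dense forward and backward.

Only what the surrogate convolutional backbone and the dropout head need.
Tensors are channels-last: (batch, height, width, channels).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d_forward", "conv2d_backward",
    "maxpool2_forward", "maxpool2_backward",
    "relu_forward", "relu_backward",
    "dense_forward", "dense_backward",
    "dropout_forward", "dropout_backward",
    "sigmoid", "bce_loss", "Adam",
]


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    # xp: padded (B, H+k-1, W+k-1, C) -> (B, H, W, k*k*C)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (B, H, W, C, k, k) -> (B, H, W, k, k, C)
    win = win.transpose(0, 1, 2, 4, 5, 3)
    b, h, w = win.shape[:3]
    return np.ascontiguousarray(win).reshape(b, h, w, -1)


def conv2d_forward(x, W, b):
    """3x3 (or any odd k) same-padding stride-1 convolution.

    W has shape (k, k, C_in, C_out).
    """
    k = W.shape[0]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    cols = _im2col(xp, k)
    out = cols @ W.reshape(-1, W.shape[-1]) + b
    return out, (cols, x.shape, W.shape)


def conv2d_backward(dout, W, cache):
    cols, x_shape, w_shape = cache
    k, _, c_in, c_out = w_shape
    pad = k // 2
    dW = np.tensordot(cols, dout, axes=([0, 1, 2], [0, 1, 2])).reshape(w_shape)
    db = dout.sum(axis=(0, 1, 2))
    dcols = dout @ W.reshape(-1, c_out).T  # (B, H, W, k*k*C_in)
    b, h, w = dout.shape[:3]
    dcols = dcols.reshape(b, h, w, k, k, c_in)
    dxp = np.zeros((b, h + 2 * pad, w + 2 * pad, c_in))
    for di in range(k):
        for dj in range(k):
            dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, di, dj, :]
    dx = dxp[:, pad:pad + h, pad:pad + w, :]
    return dx, dW, db


def maxpool2_forward(x):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""
    b, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : h2 * 2, : w2 * 2, :]
    blocks = xc.reshape(b, h2, 2, w2, 2, c)
    out = blocks.max(axis=(2, 4))
    mask = blocks == out[:, :, None, :, None, :]
    # break ties: keep only the first max in each 2x2 block
    flat = mask.transpose(0, 1, 3, 5, 2, 4).reshape(b, h2, w2, c, 4)
    first = np.cumsum(flat, axis=-1) == 1
    flat = flat & first
    mask = flat.reshape(b, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return out, (mask, x.shape)


def maxpool2_backward(dout, cache):
    mask, x_shape = cache
    b, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    dblocks = mask * dout[:, :, None, :, None, :]
    dx = np.zeros(x_shape)
    dx[:, : h2 * 2, : w2 * 2, :] = dblocks.reshape(b, h2 * 2, w2 * 2, c)
    return dx


def relu_forward(x):
    return np.maximum(x, 0.0), x > 0


def relu_backward(dout, mask):
    return dout * mask


def dense_forward(x, W, b):
    return x @ W + b, x


def dense_backward(dout, W, x):
    return dout @ W.T, x.T @ dout, dout.sum(axis=0)


def dropout_forward(x, rate, rng, train):
    if not train or rate == 0.0:
        return x, None
    keep = rng.random(x.shape) >= rate
    return x * keep / (1.0 - rate), (keep, rate)


def dropout_backward(dout, cache):
    if cache is None:
        return dout
    keep, rate = cache
    return dout * keep / (1.0 - rate)


def sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p, y, eps: float = 1e-12):
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)
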