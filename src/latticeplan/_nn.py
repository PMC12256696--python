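"""Minimal 3D convolutional network primitives (numpy, manual backprop).

Just enough machinery for a toy displacement-field encoder-decoder: 3x3x3
"same" convolutions via im2col, leaky ReLU, 2x average pooling, nearest and
linear factor-2 upsampling with exact adjoints, and Adam. Arrays are
channel-first float32: ``(C, X, Y, Z)``.
"""

from __future__ import annotations

import numpy as np

LEAK = 0.1


def he_init(rng: np.random.Generator, c_out: int, c_in: int, k: int = 3) -> np.ndarray:
    fan_in = c_in * k ** 3
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k)).astype(np.float32)


def _cols(xp: np.ndarray, k: int) -> np.ndarray:
    """(X, Y, Z, C*k^3) matrix of patches from a pre-padded (C, X+2p, ...) array."""
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # (C, X, Y, Z, k, k, k)
    win = np.moveaxis(win, 0, 3)  # (X, Y, Z, C, k, k, k)
    sh = win.shape
    return win.reshape(sh[0], sh[1], sh[2], -1)


def conv3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'same' 3D convolution (cross-correlation), kernel k x k x k."""
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    cols = _cols(xp, k)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    return np.ascontiguousarray(np.moveaxis(out, -1, 0))


def conv3_backward(x: np.ndarray, w: np.ndarray, gy: np.ndarray):
    """Gradients (gx, gw, gb) for conv3_forward."""
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    cols = _cols(xp, k).reshape(-1, ci * k ** 3)
    gym = np.moveaxis(gy, 0, -1).reshape(-1, co)
    gw = (gym.T @ cols).reshape(w.shape)
    gb = gym.sum(axis=0)
    # gx: correlate gy with spatially flipped, channel-transposed kernels
    wt = np.flip(w, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4)  # (ci, co, k, k, k)
    gyp = np.pad(gy, ((0, 0), (p, p), (p, p), (p, p)))
    gcols = _cols(gyp, k)
    gx = gcols @ wt.reshape(ci, -1).T
    return np.ascontiguousarray(np.moveaxis(gx, -1, 0)), gw, gb


def lrelu_forward(x: np.ndarray):
    neg = x < 0
    y = np.where(neg, LEAK * x, x)
    return y, neg


def lrelu_backward(gy: np.ndarray, neg: np.ndarray) -> np.ndarray:
    return np.where(neg, LEAK * gy, gy)


def avgpool2(x: np.ndarray) -> np.ndarray:
    c, nx, ny, nz = x.shape
    if nx % 2 or ny % 2 or nz % 2:
        raise ValueError(f"avgpool2 needs even spatial dims, got {(nx, ny, nz)}")
    return x.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2).mean(axis=(2, 4, 6))


def avgpool2_backward(gy: np.ndarray) -> np.ndarray:
    g = gy / 8.0
    return np.repeat(np.repeat(np.repeat(g, 2, axis=1), 2, axis=2), 2, axis=3)


def upsample2_nearest(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)


def upsample2_nearest_backward(gy: np.ndarray) -> np.ndarray:
    c, nx, ny, nz = gy.shape
    return gy.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2).sum(axis=(2, 4, 6))


def _up1d(x: np.ndarray, axis: int) -> np.ndarray:
    """Factor-2 linear upsample along one axis (cell-centered, edge-clamped).

    Output sample 2j   = 0.25 * in[j-1] + 0.75 * in[j]
    Output sample 2j+1 = 0.75 * in[j]   + 0.25 * in[j+1]
    """
    x = np.moveaxis(x, axis, -1)
    prev = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    even = 0.25 * prev + 0.75 * x
    odd = 0.75 * x + 0.25 * nxt
    out = np.stack([even, odd], axis=-1).reshape(x.shape[:-1] + (2 * x.shape[-1],))
    return np.moveaxis(out, -1, axis)


def _up1d_backward(gy: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(gy, axis, -1)
    even = g[..., 0::2]
    odd = g[..., 1::2]
    gx = 0.75 * even + 0.75 * odd
    # in[j] also feeds even sample of j+1 (weight 0.25) and odd sample of j-1
    gx[..., :-1] += 0.25 * even[..., 1:]
    gx[..., 1:] += 0.25 * odd[..., :-1]
    # edge clamping: in[0] feeds its own even sample's "prev" tap, in[-1] the odd "next" tap
    gx[..., 0] += 0.25 * even[..., 0]
    gx[..., -1] += 0.25 * odd[..., -1]
    return np.moveaxis(gx, -1, axis)


def upsample2_linear(x: np.ndarray) -> np.ndarray:
    for ax in (1, 2, 3):
        x = _up1d(x, ax)
    return x


def upsample2_linear_backward(gy: np.ndarray) -> np.ndarray:
    for ax in (3, 2, 1):
        gy = _up1d_backward(gy, ax)
    return gy


class Adam:
    def __init__(self, params: dict, lr: float = 1e-2, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
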