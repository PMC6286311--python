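"""Minimal CNN primitives (forward + backprop) on numpy arrays.

Layout is NHWC throughout; convolutions are unpadded ("valid") and
pooling strides equal the pooling kernel, so the 70-pixel input walks the
chain 70 -conv5-> 66 -pool3-> 22 -conv3-> 20 -pool2-> 10.  Arrays are
float32; all randomness comes from an explicit Generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,H,W,C) -> (N*OH*OW, C*KH*KW) patch matrix (copies)."""
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N,OH,OW,C,KH,KW)
    n, oh, ow = v.shape[:3]
    return np.ascontiguousarray(v).reshape(n * oh * ow, -1), (n, oh, ow)


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | float):
    """Valid cross-correlation. w: (KH, KW, C, F)."""
    kh, kw, c, f = w.shape
    cols, (n, oh, ow) = _im2col(x, kh, kw)
    wmat = w.transpose(2, 0, 1, 3).reshape(c * kh * kw, f)
    y = cols @ wmat
    y += b
    cache = (x, w, cols, (n, oh, ow))
    return y.reshape(n, oh, ow, f), cache


def conv_backward(dy: np.ndarray, cache, need_dx: bool = True):
    dy = np.ascontiguousarray(dy)
    x, w, cols, (n, oh, ow) = cache
    kh, kw, c, f = w.shape
    dymat = dy.reshape(n * oh * ow, f)
    dwmat = cols.T @ dymat  # (C*KH*KW, F)
    dw = dwmat.reshape(c, kh, kw, f).transpose(1, 2, 0, 3)
    db = dymat.sum(axis=0)
    if not need_dx:  # first layer: dX is never consumed
        return None, dw, db
    # dx = full correlation of dy with the flipped kernel, f as in-channel
    dyp = np.pad(dy, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0)))
    wt = w[::-1, ::-1].transpose(0, 1, 3, 2)  # (KH, KW, F, C)
    dx, _ = conv_forward(dyp, np.ascontiguousarray(wt), 0.0)
    return dx, dw, db


def maxpool_forward(x: np.ndarray, k: int):
    n, h, w, c = x.shape
    oh, ow = h // k, w // k
    xc = x[:, : oh * k, : ow * k, :]
    r = xc.reshape(n, oh, k, ow, k, c).transpose(0, 1, 3, 5, 2, 4)
    r = np.ascontiguousarray(r).reshape(n, oh, ow, c, k * k)
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return y, (x.shape, k, idx)


def maxpool_backward(dy: np.ndarray, cache):
    (n, h, w, c), k, idx = cache
    oh, ow = h // k, w // k
    dr = np.zeros((n, oh, ow, c, k * k), dtype=dy.dtype)
    np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
    dx = np.zeros((n, h, w, c), dtype=dy.dtype)
    dx[:, : oh * k, : ow * k, :] = (
        dr.reshape(n, oh, ow, c, k, k).transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, oh * k, ow * k, c)
    )
    return dx


def relu_forward(x: np.ndarray):
    return np.maximum(x, 0), x > 0


def relu_backward(dy: np.ndarray, mask: np.ndarray):
    return dy * mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray,
                 sample_weight: np.ndarray | None = None):
    """Weighted softmax cross-entropy; returns (mean loss, dlogits)."""
    n = len(y)
    p = softmax(logits)
    if sample_weight is None:
        sample_weight = np.ones(n, dtype=logits.dtype)
    wsum = sample_weight.sum()
    eps = np.finfo(logits.dtype).tiny
    loss = -(sample_weight * np.log(p[np.arange(n), y] + eps)).sum() / wsum
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (sample_weight / wsum)[:, None]
    return float(loss), dlogits


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MomentumSGD:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 momentum: float = 0.9):
        self.params = params
        self.lr, self.mu = lr, momentum
        self.v = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            self.v[k] = self.mu * self.v[k] - self.lr * g
            self.params[k] += self.v[k]
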