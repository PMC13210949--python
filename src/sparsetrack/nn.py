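"""NumPy building blocks for the encoder-only attention regressor.

Every primitive here comes as a forward returning ``(output, cache)`` and a
matching backward consuming ``(grad_output, cache)``.  Gradients are exact
(verified by finite differences in the test suite); there is no tape — the
model class composes these explicitly in reverse order.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)
LN_EPS = 1e-5


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def linear_fwd(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, (x, W)


def linear_bwd(dy: np.ndarray, cache):
    x, W = cache
    dx = dy @ W.T
    xm = x.reshape(-1, x.shape[-1])
    dym = dy.reshape(-1, dy.shape[-1])
    dW = xm.T @ dym
    db = dym.sum(axis=0)
    return dx, dW, db


def layernorm_fwd(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def layernorm_bwd(dy: np.ndarray, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    axes = tuple(range(dy.ndim - 1))
    return dx, (dy * xhat).sum(axis=axes), dy.sum(axis=axes)


def gelu_fwd(x: np.ndarray):
    phi = 0.5 * (1.0 + erf(x / _SQRT2))
    return x * phi, (x, phi)


def gelu_bwd(dy: np.ndarray, cache):
    x, phi = cache
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return dy * (phi + x * pdf)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_bwd(dy: np.ndarray, s: np.ndarray, axis: int = -1) -> np.ndarray:
    return s * (dy - (dy * s).sum(axis=axis, keepdims=True))


def dropout_fwd(x: np.ndarray, p: float, rng: np.random.Generator | None):
    """Inverted dropout; identity when rng is None (eval mode) or p == 0."""
    if rng is None or p <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


def dropout_bwd(dy: np.ndarray, mask):
    return dy if mask is None else dy * mask


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention softmax(QKᵀ/√d_k)V.

    Accepts any leading batch/head axes; the last two axes are
    (sequence, head-dim).
    """
    dk = Q.shape[-1]
    A = softmax(Q @ np.swapaxes(K, -1, -2) / np.sqrt(dk))
    return A @ V


def mhsa_fwd(x, p, prefix, n_heads, dropout_p, rng):
    """Multi-head self-attention with output projection.

    ``p`` is the parameter dict; weights live under ``{prefix}.{Wq,Wk,Wv,Wo}``
    (each d_model×d_model with bias).  Returns (out, cache).
    """
    B, L, D = x.shape
    dk = D // n_heads

    def split(h):  # (B,L,D) -> (B,H,L,dk)
        return h.reshape(B, L, n_heads, dk).transpose(0, 2, 1, 3)

    q, cq = linear_fwd(x, p[f"{prefix}.Wq"], p[f"{prefix}.bq"])
    k, ck = linear_fwd(x, p[f"{prefix}.Wk"], p[f"{prefix}.bk"])
    v, cv = linear_fwd(x, p[f"{prefix}.Wv"], p[f"{prefix}.bv"])
    Q, K, V = split(q), split(k), split(v)
    scores = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(dk)
    A = softmax(scores)
    ctx = A @ V  # (B,H,L,dk)
    merged = ctx.transpose(0, 2, 1, 3).reshape(B, L, D)
    out, co = linear_fwd(merged, p[f"{prefix}.Wo"], p[f"{prefix}.bo"])
    out, dmask = dropout_fwd(out, dropout_p, rng)
    return out, (cq, ck, cv, Q, K, V, A, co, dmask, n_heads)


def mhsa_bwd(dy, cache, prefix, grads):
    cq, ck, cv, Q, K, V, A, co, dmask, n_heads = cache
    B, H, L, dk = Q.shape
    D = H * dk
    dy = dropout_bwd(dy, dmask)
    dmerged, dWo, dbo = linear_bwd(dy, co)
    grads[f"{prefix}.Wo"] += dWo
    grads[f"{prefix}.bo"] += dbo
    dctx = dmerged.reshape(B, L, H, dk).transpose(0, 2, 1, 3)
    dA = dctx @ V.transpose(0, 1, 3, 2)
    dV = A.transpose(0, 1, 3, 2) @ dctx
    dscores = softmax_bwd(dA, A) / np.sqrt(dk)
    dQ = dscores @ K
    dK = dscores.transpose(0, 1, 3, 2) @ Q

    def merge(h):  # (B,H,L,dk) -> (B,L,D)
        return h.transpose(0, 2, 1, 3).reshape(B, L, D)

    dx = np.zeros_like(dy)
    for dh, c, name in ((dQ, cq, "q"), (dK, ck, "k"), (dV, cv, "v")):
        dxi, dW, db = linear_bwd(merge(dh), c)
        grads[f"{prefix}.W{name}"] += dW
        grads[f"{prefix}.b{name}"] += db
        dx += dxi
    return dx


def positional_encoding(L: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional-encoding table of shape (L, d_model).

    PE(pos, 2i) = sin(pos / 10000^(2i/d_model)), PE(pos, 2i+1) = cos(·); the
    continuous phase lets attention measure temporal offsets between frames.
    """
    if L <= 0 or d_model <= 0:
        raise ValueError("positional encoding dims must be positive")
    pos = np.arange(L)[:, None]
    i = np.arange(0, d_model, 2)[None, :]
    angle = pos / np.power(10000.0, i / d_model)
    pe = np.zeros((L, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : pe[:, 1::2].shape[1]])
    return pe


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            # decay only matrices, not biases/gains
            if params[k].ndim > 1:
                update = update + self.wd * params[k]
            params[k] -= self.lr * update
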