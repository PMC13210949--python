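"""Encoder-only attention regressor: 120-frame feature window → 40-dim pose.

The network maps an ``(L, 50)`` normalized sensor window to the kinematic
state of the four uninstrumented proximal joints: per joint a swing
quaternion (L2-normalized before loss and output), an angular velocity, and
a linear acceleration.  Architecture: linear input embedding 50→d_model,
added sinusoidal positional encoding, N pre-layer-norm encoder blocks
(multi-head self-attention + residual, GELU feed-forward + residual), a
final layer norm, and four parallel per-joint linear heads reading the
latent state of the last frame only (sequence-to-vector, zero look-ahead).

Implemented in NumPy with explicit backward passes (see
:mod:`sparsetrack.nn`); ``forward(..., dropout_rng=...)`` enables training
mode, eval mode is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

N_JOINTS = 4
JOINT_DIM = 10  # swing 4 + ω 3 + a 3


@dataclass
class ModelConfig:
    d_model: int = 256
    n_layers: int = 6
    n_heads: int = 8
    d_ff: int = 1024
    dropout: float = 0.1
    L: int = 120
    d_in: int = 50
    d_out: int = 40

    def __post_init__(self):
        for name in ("d_model", "n_layers", "n_heads", "d_ff", "L", "d_in", "d_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.d_out != N_JOINTS * JOINT_DIM:
            raise ValueError(f"d_out must be {N_JOINTS * JOINT_DIM}")

    @classmethod
    def reduced(cls, **kw) -> "ModelConfig":
        """Desk-scale configuration for CPU training."""
        base = dict(d_model=64, n_layers=2, n_heads=4, d_ff=256)
        base.update(kw)
        return cls(**base)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class TransformerRegressor:
    """The attention network with explicit forward/backward over a parameter
    dict.  ``seed`` fixes the weight initialization."""

    def __init__(self, config: ModelConfig, seed: int = 42):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        p: dict[str, np.ndarray] = {}
        p["embed.W"] = _glorot(rng, c.d_in, c.d_model)
        p["embed.b"] = np.zeros(c.d_model)
        for i in range(c.n_layers):
            pre = f"layers.{i}"
            for nm in ("q", "k", "v", "o"):
                p[f"{pre}.attn.W{nm}"] = _glorot(rng, c.d_model, c.d_model)
                p[f"{pre}.attn.b{nm}"] = np.zeros(c.d_model)
            p[f"{pre}.ln1.g"] = np.ones(c.d_model)
            p[f"{pre}.ln1.b"] = np.zeros(c.d_model)
            p[f"{pre}.ln2.g"] = np.ones(c.d_model)
            p[f"{pre}.ln2.b"] = np.zeros(c.d_model)
            p[f"{pre}.ffn.W1"] = _glorot(rng, c.d_model, c.d_ff)
            p[f"{pre}.ffn.b1"] = np.zeros(c.d_ff)
            p[f"{pre}.ffn.W2"] = _glorot(rng, c.d_ff, c.d_model)
            p[f"{pre}.ffn.b2"] = np.zeros(c.d_model)
        p["final_ln.g"] = np.ones(c.d_model)
        p["final_ln.b"] = np.zeros(c.d_model)
        for j in range(N_JOINTS):
            p[f"head.{j}.W"] = _glorot(rng, c.d_model, JOINT_DIM)
            p[f"head.{j}.b"] = np.zeros(JOINT_DIM)
        self.params = p
        self.pe = nn.positional_encoding(c.L, c.d_model)
        self._cache = None

    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward ------------------------------------------------------------

    def forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None,
                keep_cache: bool = False) -> np.ndarray:
        """Predict (B, 4, 10) joint blocks from (B, L, 50) windows.

        Passing ``dropout_rng`` enables dropout (training mode) and caches
        intermediates for :meth:`backward`; without it the pass is
        deterministic.
        """
        c, p = self.config, self.params
        if X.ndim != 3 or X.shape[1:] != (c.L, c.d_in):
            raise ValueError(f"expected window shape (B, {c.L}, {c.d_in}), got {X.shape}")
        drop = c.dropout if dropout_rng is not None else 0.0
        caches = []
        h = X @ p["embed.W"] + p["embed.b"] + self.pe
        for i in range(c.n_layers):
            pre = f"layers.{i}"
            a, c_ln1 = nn.layernorm_fwd(h, p[f"{pre}.ln1.g"], p[f"{pre}.ln1.b"])
            attn, c_attn = nn.mhsa_fwd(a, p, f"{pre}.attn", c.n_heads, drop, dropout_rng)
            h = h + attn
            f, c_ln2 = nn.layernorm_fwd(h, p[f"{pre}.ln2.g"], p[f"{pre}.ln2.b"])
            u1, c_l1 = nn.linear_fwd(f, p[f"{pre}.ffn.W1"], p[f"{pre}.ffn.b1"])
            g, c_g = nn.gelu_fwd(u1)
            u2, c_l2 = nn.linear_fwd(g, p[f"{pre}.ffn.W2"], p[f"{pre}.ffn.b2"])
            u2, dmask = nn.dropout_fwd(u2, drop, dropout_rng)
            h = h + u2
            caches.append((c_ln1, c_attn, c_ln2, c_l1, c_g, c_l2, dmask))
        hN, c_fln = nn.layernorm_fwd(h, p["final_ln.g"], p["final_ln.b"])
        z = hN[:, -1, :]
        raw = np.stack(
            [z @ p[f"head.{j}.W"] + p[f"head.{j}.b"] for j in range(N_JOINTS)], axis=1
        )  # (B, 4, 10)
        s = raw[..., :4]
        norm = np.linalg.norm(s, axis=-1, keepdims=True)
        norm = np.maximum(norm, 1e-12)
        out = raw.copy()
        out[..., :4] = s / norm
        if dropout_rng is not None or keep_cache:
            self._cache = (X, caches, c_fln, z, out, norm, h.shape)
        return out

    # -- backward -----------------------------------------------------------

    def backward(self, d_out: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters given its
        gradient w.r.t. the forward output (swing block gradient expressed
        w.r.t. the *normalized* quaternions)."""
        if self._cache is None:
            raise RuntimeError("forward(...) with dropout_rng/keep_cache must precede backward")
        X, caches, c_fln, z, out, norm, hshape = self._cache
        c, p = self.config, self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        d_raw = d_out.copy()
        q = out[..., :4]
        dq = d_out[..., :4]
        d_raw[..., :4] = (dq - q * np.sum(q * dq, axis=-1, keepdims=True)) / norm

        dz = np.zeros_like(z)
        for j in range(N_JOINTS):
            dyj = d_raw[:, j, :]
            dz += dyj @ p[f"head.{j}.W"].T
            grads[f"head.{j}.W"] += z.T @ dyj
            grads[f"head.{j}.b"] += dyj.sum(axis=0)

        dhN = np.zeros(hshape)
        dhN[:, -1, :] = dz
        dh, dg, db = nn.layernorm_bwd(dhN, c_fln)
        grads["final_ln.g"] += dg
        grads["final_ln.b"] += db

        for i in reversed(range(c.n_layers)):
            pre = f"layers.{i}"
            c_ln1, c_attn, c_ln2, c_l1, c_g, c_l2, dmask = caches[i]
            du2 = nn.dropout_bwd(dh, dmask)
            dgelu, dW2, db2 = nn.linear_bwd(du2, c_l2)
            grads[f"{pre}.ffn.W2"] += dW2
            grads[f"{pre}.ffn.b2"] += db2
            du1 = nn.gelu_bwd(dgelu, c_g)
            df, dW1, db1 = nn.linear_bwd(du1, c_l1)
            grads[f"{pre}.ffn.W1"] += dW1
            grads[f"{pre}.ffn.b1"] += db1
            dh2, dg2, db2n = nn.layernorm_bwd(df, c_ln2)
            grads[f"{pre}.ln2.g"] += dg2
            grads[f"{pre}.ln2.b"] += db2n
            dh = dh + dh2  # residual
            da = nn.mhsa_bwd(dh, c_attn, f"{pre}.attn", grads)
            dh1, dg1, db1n = nn.layernorm_bwd(da, c_ln1)
            grads[f"{pre}.ln1.g"] += dg1
            grads[f"{pre}.ln1.b"] += db1n
            dh = dh + dh1

        Xm = X.reshape(-1, c.d_in)
        dhm = dh.reshape(-1, c.d_model)
        grads["embed.W"] += Xm.T @ dhm
        grads["embed.b"] += dhm.sum(axis=0)
        return grads

    # -- checkpointing ------------------------------------------------------

    def save(self, path, extra: dict | None = None) -> None:
        """Single-file checkpoint: weights + config + arbitrary JSON extras
        (normalization statistics, run seed, ...)."""
        meta = {"schema": 1, "config": asdict(self.config), "extra": extra or {}}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path):
        """Returns ``(model, extra_dict)``."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("schema") != 1:
                raise ValueError(f"unsupported checkpoint schema: {meta.get('schema')}")
            model = cls(ModelConfig(**meta["config"]))
            for k in model.params:
                model.params[k] = data[k].copy()
        return model, meta["extra"]
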