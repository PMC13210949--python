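"""Stream sanitization, normalization, windowing and target construction.

The pipeline consumes five time-synchronized 60 Hz IMU streams (both wrists,
both ankles, torso), each contributing a 10-dim block per frame — unit
quaternion (4), angular velocity (3, rad/s), linear acceleration (3, m/s²) —
concatenated into a 50-dim feature vector.  Quaternion blocks are strictly
L2-normalized; inertial blocks are z-normalized with a single pooled (μ, σ)
per sensor × modality (shared across the three spatial axes, preserving
directional structure) and clamped to ±5, which retains ≈99.9999% of a
Gaussian while removing non-biological transients.

Prediction targets cover the four uninstrumented proximal joints (upper arms
and upper legs): the swing component of the proximal-relative-to-distal
rotation about the anatomical limb axis [1,0,0], plus proximal angular
velocity and linear acceleration, 40 values per frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import quat

SENSORS = ("left_wrist", "right_wrist", "left_ankle", "right_ankle", "torso")
JOINTS = ("left_upper_arm", "right_upper_arm", "left_upper_leg", "right_upper_leg")
MODALITIES = ("gyro", "acc")

FRAME_DIM = 50  # 5 sensors × (4 quat + 3 ω + 3 a)
TARGET_DIM = 40  # 4 joints × (4 swing + 3 ω + 3 a)
RATE_HZ = 60.0
CLAMP = 5.0
EPS = 1e-8

STREAM_COLUMNS = ["time", "sensor", "qw", "qx", "qy", "qz", "wx", "wy", "wz", "ax", "ay", "az"]


class StreamFormatError(ValueError):
    """Raised for malformed sensor stream files (schema or time ordering)."""


class StreamRejected(ValueError):
    """Raised when a stream fails the numerical-anomaly screen."""


@dataclass
class SensorStream:
    """Time-synchronized multi-sensor recording at a nominal 60 Hz.

    Arrays are indexed ``[frame, sensor, component]`` with the sensor axis in
    the fixed order of :data:`SENSORS`.
    """

    time: np.ndarray  # (T,)
    quat: np.ndarray  # (T, 5, 4)
    gyro: np.ndarray  # (T, 5, 3) rad/s
    acc: np.ndarray  # (T, 5, 3) m/s²

    def __len__(self) -> int:
        return self.time.shape[0]

    def copy(self) -> "SensorStream":
        return SensorStream(self.time.copy(), self.quat.copy(), self.gyro.copy(), self.acc.copy())

    def to_csv(self, path) -> None:
        """Write the long-format CSV: one row per sensor per tick."""
        T = len(self)
        rows = {
            "time": np.repeat(self.time, len(SENSORS)),
            "sensor": np.tile(np.array(SENSORS), T),
        }
        flat_q = self.quat.reshape(T * len(SENSORS), 4)
        flat_w = self.gyro.reshape(T * len(SENSORS), 3)
        flat_a = self.acc.reshape(T * len(SENSORS), 3)
        for i, c in enumerate(["qw", "qx", "qy", "qz"]):
            rows[c] = flat_q[:, i]
        for i, c in enumerate(["wx", "wy", "wz"]):
            rows[c] = flat_w[:, i]
        for i, c in enumerate(["ax", "ay", "az"]):
            rows[c] = flat_a[:, i]
        pd.DataFrame(rows)[STREAM_COLUMNS].to_csv(path, index=False)

    def to_npz(self, path) -> None:
        """Columnar binary container — same content as the CSV, faster I/O."""
        np.savez_compressed(path, time=self.time, quat=self.quat, gyro=self.gyro, acc=self.acc)

    @classmethod
    def from_npz(cls, path) -> "SensorStream":
        with np.load(path) as d:
            return cls(d["time"].copy(), d["quat"].copy(), d["gyro"].copy(), d["acc"].copy())

    @classmethod
    def from_csv(cls, path) -> "SensorStream":
        df = pd.read_csv(path)
        missing = set(STREAM_COLUMNS) - set(df.columns)
        if missing:
            raise StreamFormatError(f"stream file missing columns: {sorted(missing)}")
        times = np.asarray(sorted(df["time"].unique()), dtype=float)
        T = times.shape[0]
        q = np.full((T, len(SENSORS), 4), np.nan)
        w = np.full((T, len(SENSORS), 3), np.nan)
        a = np.full((T, len(SENSORS), 3), np.nan)
        t_index = {t: i for i, t in enumerate(times)}
        s_index = {s: i for i, s in enumerate(SENSORS)}
        unknown = set(df["sensor"].unique()) - set(SENSORS)
        if unknown:
            raise StreamFormatError(f"unknown sensors in stream: {sorted(unknown)}")
        ti = df["time"].map(t_index).to_numpy()
        si = df["sensor"].map(s_index).to_numpy()
        q[ti, si] = df[["qw", "qx", "qy", "qz"]].to_numpy()
        w[ti, si] = df[["wx", "wy", "wz"]].to_numpy()
        a[ti, si] = df[["ax", "ay", "az"]].to_numpy()
        return cls(times, q, w, a)


@dataclass
class RejectionReport:
    """Why a stream failed sanitization."""

    reason: str
    n_bad_frames: int
    longest_gap: int


def _bad_frame_mask(stream: SensorStream) -> np.ndarray:
    """Frames containing any NaN/Inf in any channel of any sensor."""
    bad_q = ~np.isfinite(stream.quat).all(axis=(1, 2))
    bad_w = ~np.isfinite(stream.gyro).all(axis=(1, 2))
    bad_a = ~np.isfinite(stream.acc).all(axis=(1, 2))
    return bad_q | bad_w | bad_a


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for b in mask:
        run = run + 1 if b else 0
        best = max(best, run)
    return best


def sanitize_stream(stream: SensorStream, max_gap: int = 3):
    """Screen a stream for numerical anomalies.

    Frames with +/-Inf anywhere, or NaN gaps of ``max_gap`` or more
    consecutive frames, cause rejection of the whole file (returns a
    :class:`RejectionReport`).  Shorter isolated NaN gaps are repaired:
    normalized linear interpolation for quaternions, linear interpolation
    for inertial channels.  Returns the cleaned :class:`SensorStream` on
    success.  Non-monotonic timestamps raise :class:`StreamFormatError`.
    """
    if np.any(np.diff(stream.time) <= 0):
        raise StreamFormatError("non-monotonic timestamps")
    has_inf = (
        np.isinf(stream.quat).any() or np.isinf(stream.gyro).any() or np.isinf(stream.acc).any()
    )
    bad = _bad_frame_mask(stream)
    longest = _longest_run(bad)
    if has_inf:
        return RejectionReport("infinite values present", int(bad.sum()), longest)
    if bad[0] or bad[-1]:
        return RejectionReport("NaN at stream boundary", int(bad.sum()), longest)
    if longest >= max_gap:
        return RejectionReport(
            f"NaN gap of {longest} frames exceeds max_gap={max_gap}", int(bad.sum()), longest
        )
    if not bad.any():
        return stream
    out = stream.copy()
    T = len(out)
    good = np.flatnonzero(~bad)
    for t in np.flatnonzero(bad):
        lo = good[good < t][-1]
        hi = good[good > t][0]
        frac = (t - lo) / (hi - lo)
        out.gyro[t] = (1 - frac) * out.gyro[lo] + frac * out.gyro[hi]
        out.acc[t] = (1 - frac) * out.acc[lo] + frac * out.acc[hi]
        qa, qb = out.quat[lo], out.quat[hi]
        # shortest-arc nlerp: align hemispheres before blending
        dot = np.sum(qa * qb, axis=-1, keepdims=True)
        qb = np.where(dot < 0, -qb, qb)
        out.quat[t] = quat.normalize((1 - frac) * qa + frac * qb)
    assert T == len(out)
    return out


@dataclass
class NormStats:
    """Pooled per-sensor, per-modality normalization statistics.

    ``mu``/``sigma`` have shape (5 sensors, 2 modalities) where modality 0 is
    angular velocity and 1 is linear acceleration.  One scalar pair covers
    all three spatial axes of a modality, so relative axis directions are
    preserved.  Computed from the training partition only.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def to_dict(self) -> dict:
        return {"mu": self.mu.tolist(), "sigma": self.sigma.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(np.asarray(d["mu"], dtype=float), np.asarray(d["sigma"], dtype=float))


@dataclass
class TargetStats:
    """Pooled per-joint statistics for target ω and a, shape (4, 2)."""

    mu: np.ndarray
    sigma: np.ndarray

    def to_dict(self) -> dict:
        return {"mu": self.mu.tolist(), "sigma": self.sigma.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TargetStats":
        return cls(np.asarray(d["mu"], dtype=float), np.asarray(d["sigma"], dtype=float))


def compute_norm_stats(streams: Sequence[SensorStream], sigma_floor: float = EPS) -> NormStats:
    """Pool all frames and all three axes per sensor × modality (Eq.-style
    scalar global mean/std); σ is floored at ``sigma_floor``."""
    if not streams:
        raise ValueError("empty training collection")
    gyro = np.concatenate([s.gyro for s in streams], axis=0)  # (ΣT, 5, 3)
    acc = np.concatenate([s.acc for s in streams], axis=0)
    mu = np.stack([gyro.mean(axis=(0, 2)), acc.mean(axis=(0, 2))], axis=-1)
    sigma = np.stack([gyro.std(axis=(0, 2)), acc.std(axis=(0, 2))], axis=-1)
    sigma = np.maximum(sigma, sigma_floor)
    return NormStats(mu=mu, sigma=sigma)


def znorm_clamp(x: np.ndarray, mu, sigma) -> np.ndarray:
    """Standardize then clamp to [−5, 5]."""
    return np.clip((np.asarray(x, dtype=float) - mu) / (np.asarray(sigma) + EPS), -CLAMP, CLAMP)


def assemble_features(stream: SensorStream, stats: NormStats) -> np.ndarray:
    """Build the (T, 50) feature matrix from a sanitized stream.

    Per frame, five 10-dim sensor blocks in :data:`SENSORS` order:
    L2-normalized quaternion, then z-normalized-and-clamped ω and a.  Only
    the frame's own measurements enter its features (strict causality).
    """
    if stream.quat.shape[1] != len(SENSORS):
        raise StreamFormatError(
            f"expected {len(SENSORS)} sensors, got {stream.quat.shape[1]}"
        )
    q = quat.normalize(stream.quat)  # (T,5,4)
    w = znorm_clamp(stream.gyro, stats.mu[:, 0, None], stats.sigma[:, 0, None])
    a = znorm_clamp(stream.acc, stats.mu[:, 1, None], stats.sigma[:, 1, None])
    blocks = np.concatenate([q, w, a], axis=-1)  # (T, 5, 10)
    out = blocks.reshape(len(stream), FRAME_DIM)
    return out


def compute_target_stats(
    omega: np.ndarray, acc: np.ndarray, sigma_floor: float = EPS
) -> TargetStats:
    """Pooled stats of proximal-joint ω (T,4,3) and a (T,4,3) over frames and axes."""
    mu = np.stack([omega.mean(axis=(0, 2)), acc.mean(axis=(0, 2))], axis=-1)
    sigma = np.stack([omega.std(axis=(0, 2)), acc.std(axis=(0, 2))], axis=-1)
    return TargetStats(mu=mu, sigma=np.maximum(sigma, sigma_floor))


def make_training_target(
    q_proximal: np.ndarray,
    q_distal: np.ndarray,
    omega: np.ndarray,
    acc: np.ndarray,
    target_stats: TargetStats | None = None,
) -> np.ndarray:
    """Build the (..., 4, 10) per-joint target blocks.

    The orientation target is the swing component of
    ``q_rel = q_proximal ⊗ q_distal⁻¹`` about the limb axis [1,0,0] —
    axial twist, dominated by wrist-sensor noise in sparse setups, is
    excluded from supervision.  ω and a are z-normalized with the
    proximal-joint training statistics when provided.
    """
    q_rel = quat.relative_rotation(q_proximal, q_distal)
    st = quat.swing_twist_decompose(q_rel, axis=(1.0, 0.0, 0.0))
    if target_stats is not None:
        omega = znorm_clamp(omega, target_stats.mu[:, 0, None], target_stats.sigma[:, 0, None])
        acc = znorm_clamp(acc, target_stats.mu[:, 1, None], target_stats.sigma[:, 1, None])
    return np.concatenate([st.swing, omega, acc], axis=-1)


def flatten_targets(blocks: np.ndarray) -> np.ndarray:
    """(..., 4, 10) per-joint blocks → (..., 40) target vectors."""
    return blocks.reshape(blocks.shape[:-2] + (TARGET_DIM,))


def sliding_windows(
    features: np.ndarray, targets: np.ndarray | None, L: int = 120, stride: int = 30
):
    """Segment (T, 50) features into (N, L, 50) windows with zero look-ahead.

    Window n covers frames [n·stride, n·stride+L); its target is taken at
    the window's final frame.  N = floor((T−L)/stride) + 1; series shorter
    than L yield empty output.
    """
    T = features.shape[0]
    if T < L:
        n = 0
    else:
        n = (T - L) // stride + 1
    idx = np.arange(n) * stride
    wins = np.stack([features[i : i + L] for i in idx]) if n else np.empty((0, L, FRAME_DIM))
    if targets is None:
        return wins
    tgts = targets[idx + L - 1] if n else np.empty((0,) + targets.shape[1:])
    return wins, tgts


HARD_NEGATIVE_OMEGA_LIMIT = 0.1  # rad/s, strict


def hard_negative_validity(proximal_omega: np.ndarray) -> bool:
    """True iff every proximal joint stays below the strict 0.1 rad/s
    angular-speed tolerance in every frame (‖ω‖ < 0.1, exact boundary
    excluded)."""
    speed = np.linalg.norm(np.asarray(proximal_omega, dtype=float), axis=-1)
    return bool(np.max(speed) < HARD_NEGATIVE_OMEGA_LIMIT)


def hard_negatives_per_batch(batch_size: int, r: float) -> int:
    """Hard-negative count: banker's rounding of r·batch_size, floored at 1
    whenever r > 0."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"mixing ratio r must be in [0, 1], got {r}")
    if r == 0.0:
        return 0
    n = int(np.round(r * batch_size))  # numpy rounds half to even
    return max(n, 1)


def mix_batches(
    n_adl: int, n_hard: int, batch_size: int = 64, r: float = 0.1, seed: int = 42
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield one epoch of mixed batch indices.

    Each batch holds ``hard_negatives_per_batch(batch_size, r)`` indices
    drawn without replacement from the hard-negative pool (cycled if the
    pool is smaller than the epoch's demand) and the balance from the ADL
    pool, reshuffled per call from ``seed``.  Yields
    ``(adl_indices, hard_indices)`` pairs.
    """
    if n_adl <= 0:
        raise ValueError("ADL pool is empty")
    k = hard_negatives_per_batch(batch_size, r)
    if k > 0 and n_hard <= 0:
        raise ValueError("hard-negative pool is empty but r > 0")
    rng = np.random.default_rng(seed)
    adl_order = rng.permutation(n_adl)
    hard_order = rng.permutation(n_hard) if n_hard else np.empty(0, dtype=int)
    n_batches = n_adl // (batch_size - k)
    hard_pos = 0
    for b in range(n_batches):
        adl_idx = adl_order[b * (batch_size - k) : (b + 1) * (batch_size - k)]
        take = []
        while len(take) < k:
            if hard_pos == len(hard_order):
                hard_order = rng.permutation(n_hard)
                hard_pos = 0
            take.append(hard_order[hard_pos])
            hard_pos += 1
        yield adl_idx, np.asarray(take, dtype=int)


@dataclass
class Manifest:
    """Dataset manifest: file list with labels and partitions."""

    entries: list = field(default_factory=list)

    def add(self, path: str, label: str, partition: str) -> None:
        if label not in ("adl", "hard_negative") and not label.startswith("hard_negative:"):
            raise ValueError(f"bad label {label!r}")
        if partition not in ("train", "val", "test"):
            raise ValueError(f"bad partition {partition!r}")
        self.entries.append({"path": path, "label": label, "partition": partition})

    def files(self, partition: str | None = None, label_prefix: str | None = None) -> list:
        out = self.entries
        if partition is not None:
            out = [e for e in out if e["partition"] == partition]
        if label_prefix is not None:
            out = [e for e in out if e["label"].startswith(label_prefix)]
        return out

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({"files": self.entries}, indent=2))

    @classmethod
    def load(cls, path) -> "Manifest":
        data = json.loads(Path(path).read_text())
        m = cls()
        m.entries = list(data["files"])
        return m
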