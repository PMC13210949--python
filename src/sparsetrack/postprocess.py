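"""Anatomical joint-limit clamping and multiplicative Kalman smoothing.

Raw per-frame network predictions can exceed physiological joint ranges and
carry frame-to-frame jitter.  Post-processing applies, in order:

1. deterministic clamping of each predicted relative rotation inside a
   per-joint Euler bounding box (hinge joints bound a single flexion axis),
   re-projected back onto SO(3); then
2. a scalar-gain multiplicative extended Kalman filter (MEKF) that blends
   each new observation with the running estimate through the SO(3)
   log/exp maps, assuming approximately isotropic rotational uncertainty.

Clamping precedes filtering so the smoothed trajectory never jumps from a
late limit violation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from . import quat


@dataclass(frozen=True)
class JointLimits:
    """Euler bounding box for one joint.

    ``order`` is the intrinsic rotation order (scipy uppercase convention);
    ``bounds_deg`` gives (lower, upper) per axis, lower < upper except for
    locked axes which use a degenerate (v, v) pair.  A hinge joint is a box
    with its two off-axes locked at 0°.
    """

    order: str
    bounds_deg: tuple

    def __post_init__(self):
        if len(self.bounds_deg) != len(self.order):
            raise ValueError("one (lo, hi) pair per rotation axis required")
        for lo, hi in self.bounds_deg:
            if lo > hi:
                raise ValueError(f"lower bound {lo} exceeds upper {hi}")


def default_joint_limits() -> dict[str, JointLimits]:
    """Shipped defaults: elbow hinge flexion in [5°, 150°]; shoulder (and,
    mirroring it, hip) bounded in [−45°, 150°] on all three axes.  Editable
    via the packaged ``joint_limits.json``."""
    raw = json.loads(
        resources.files("sparsetrack.data").joinpath("joint_limits.json").read_text()
    )
    return {
        name: JointLimits(order=spec["order"], bounds_deg=tuple(map(tuple, spec["bounds_deg"])))
        for name, spec in raw.items()
    }


def clamp_joint_limits(q_rel: np.ndarray, limits: JointLimits) -> np.ndarray:
    """Clamp relative rotations (..., 4) inside the joint's Euler box.

    The quaternion is mapped to the joint-aligned intrinsic Euler
    parameterization, each angle clipped to its bounds, and the result
    re-projected onto SO(3).  In-range rotations are fixed points; the
    operation is idempotent.  Joint frames are assumed pre-aligned during
    calibration so Euler singularities lie outside the anatomical range.
    """
    q = np.asarray(q_rel, dtype=float)
    shape = q.shape
    flat = q.reshape(-1, 4)
    # scipy is x,y,z,w ordered
    rot = Rotation.from_quat(flat[:, [1, 2, 3, 0]])
    eul = rot.as_euler(limits.order, degrees=True)
    lo = np.array([b[0] for b in limits.bounds_deg])
    hi = np.array([b[1] for b in limits.bounds_deg])
    eul = np.clip(eul, lo, hi)
    out = Rotation.from_euler(limits.order, eul, degrees=True).as_quat()
    return quat.canonicalize(out[:, [3, 0, 1, 2]].reshape(shape))


@dataclass
class FilterState:
    """Scalar-covariance MEKF state for one joint.

    ``P`` starts at the measurement noise variance; process noise σ_p² and
    measurement noise σ_m² are constants, yielding a stationary gain
    K ≈ 0.03 (a ~0.5 s low-pass at 60 Hz) after transient decay.
    """

    q_hat: np.ndarray
    P: float = 1e-3
    sigma_p2: float = 1e-6
    sigma_m2: float = 1e-3

    def __post_init__(self):
        if self.P < 0:
            raise ValueError("covariance must be non-negative")


def mekf_update(state: FilterState, q_obs: np.ndarray) -> FilterState:
    """One multiplicative Kalman step.

    Gain K = (P + σ_p²)/(P + σ_p² + σ_m²); the rotational residual
    log(q_obs ⊗ q̂⁻¹) is scaled by K in the tangent space and re-applied by
    the exponential map, so the update is a geodesic interpolation from the
    prior toward the observation and the estimate stays on S³ exactly.
    Covariance propagates as P⁺ = (1 − K)(P + σ_p²).
    """
    S = state.P + state.sigma_p2
    K = S / (S + state.sigma_m2)
    resid = quat.quat_log(quat.hamilton_product(q_obs, quat.quat_inverse(state.q_hat)))
    q_new = quat.hamilton_product(quat.quat_exp(K * resid), state.q_hat)
    q_new = quat.normalize(q_new)
    return replace(state, q_hat=q_new, P=(1.0 - K) * S)


def mekf_smooth(
    q_series: np.ndarray, sigma_p2: float = 1e-6, sigma_m2: float = 1e-3
) -> np.ndarray:
    """Filter a (T, ..., 4) quaternion series causally, one MEKF per
    trailing joint slot, initialized at the first observation."""
    q_series = np.asarray(q_series, dtype=float)
    T = q_series.shape[0]
    flat = q_series.reshape(T, -1, 4)
    out = np.empty_like(flat)
    for j in range(flat.shape[1]):
        st = FilterState(q_hat=flat[0, j], P=sigma_m2, sigma_p2=sigma_p2, sigma_m2=sigma_m2)
        out[0, j] = flat[0, j]
        for t in range(1, T):
            st = mekf_update(st, flat[t, j])
            out[t, j] = st.q_hat
    return out.reshape(q_series.shape)


def apply_postprocessing(
    swing: np.ndarray,
    joint_names: tuple,
    limits: dict[str, JointLimits] | None = None,
    clamp: bool = True,
    smooth: bool = True,
    sigma_p2: float = 1e-6,
    sigma_m2: float = 1e-3,
) -> np.ndarray:
    """Full inference-time stack on a (T, J, 4) swing series: limits first,
    then MEKF smoothing.  Either stage can be disabled for ablation."""
    out = np.asarray(swing, dtype=float).copy()
    if clamp:
        if limits is None:
            limits = default_joint_limits()
        for j, name in enumerate(joint_names):
            if name in limits:
                out[:, j] = clamp_joint_limits(out[:, j], limits[name])
    if smooth:
        out = mekf_smooth(out, sigma_p2=sigma_p2, sigma_m2=sigma_m2)
    return out
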