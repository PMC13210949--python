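"""Quaternion algebra, frame calibration, and swing-twist decomposition.

All quaternions are w-first ``[w, x, y, z]`` unit 4-vectors in the Hamilton
convention.  Composition ``hamilton_product(q1, q2)`` means "apply q2 first,
then q1" — the convention under which a boresight offset is applied by
pre-multiplication, ``q_calibrated = q_offset ⊗ q_global``.

Every function is vectorized over leading axes: inputs of shape ``(..., 4)``
(or ``(..., 3)`` for tangent vectors) are processed element-wise on the
trailing axis.  ``q`` and ``-q`` encode the same rotation (double cover of
SO(3)); functions here never silently canonicalize signs — use
:func:`canonicalize` explicitly at serialization boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IDENTITY",
    "SwingTwist",
    "avatar_calibration",
    "boresight_calibrate",
    "canonicalize",
    "coord_permute",
    "geodesic_error_deg",
    "hamilton_product",
    "normalize",
    "quat_exp",
    "quat_inverse",
    "quat_log",
    "relative_rotation",
    "swing_twist_decompose",
    "from_axis_angle",
    "rotate_vector",
    "random_unit",
]

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

# Twist-norm threshold below which the relative rotation is a pure 180° swing
# orthogonal to the twist axis; the decomposition is singular there.
_TWIST_EPS = 1e-12


def _check_finite(q: np.ndarray, name: str = "quaternion") -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError(f"non-finite values in {name}")
    return q


def normalize(q: np.ndarray) -> np.ndarray:
    """Project onto the unit hypersphere S³; raises on zero norm."""
    q = _check_finite(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < _TWIST_EPS):
        raise ValueError("cannot normalize zero quaternion")
    return q / n


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Flip sign so w ≥ 0.  Same rotation, single representative."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0.0, -1.0, 1.0)
    return q * sign


def hamilton_product(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton composition q1 ⊗ q2 (apply q2, then q1)."""
    q1 = _check_finite(q1, "q1")
    q2 = _check_finite(q2, "q2")
    w1, x1, y1, z1 = (q1[..., i] for i in range(4))
    w2, x2, y2, z2 = (q2[..., i] for i in range(4))
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_inverse(q: np.ndarray) -> np.ndarray:
    """Conjugate ``[w, -x, -y, -z]`` — the inverse for unit quaternions."""
    q = _check_finite(q)
    if np.any(np.linalg.norm(q, axis=-1) < _TWIST_EPS):
        raise ValueError("cannot invert zero quaternion")
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def coord_permute(q_raw: np.ndarray, segment_class: str) -> np.ndarray:
    """Map raw right-handed ENU sensor quaternions into the left-handed
    Y-up global frame.

    ``[w,x,y,z] → [w,y,-x,z]`` for upper-body segments and ``[w,y,-x,-z]``
    for lower-body segments; the z-sign difference absorbs the mounting
    orientation of lower-limb sensors relative to the proximal joint axis.
    """
    q_raw = _check_finite(q_raw)
    w, x, y, z = (q_raw[..., i] for i in range(4))
    if segment_class == "upper":
        return np.stack([w, y, -x, z], axis=-1)
    if segment_class == "lower":
        return np.stack([w, y, -x, -z], axis=-1)
    raise ValueError(f"unknown segment class: {segment_class!r}")


def boresight_calibrate(q_global_t: np.ndarray, q_offset: np.ndarray) -> np.ndarray:
    """Apply a static T-pose boresight offset: q_offset ⊗ q_global(t).

    With ``q_offset = quat_inverse(q_global(t0))`` the output is the identity
    rotation at the calibration instant, removing sensor mounting bias.
    """
    return hamilton_product(q_offset, q_global_t)


def relative_rotation(q_proximal: np.ndarray, q_distal: np.ndarray) -> np.ndarray:
    """Joint articulation q_rel = q_proximal ⊗ q_distal⁻¹, isolating the
    proximal-to-distal relative rotation from shared global heading."""
    return hamilton_product(q_proximal, quat_inverse(q_distal))


@dataclass(frozen=True)
class SwingTwist:
    """Factorization q_rel = swing ⊗ twist about an anatomical axis.

    ``twist`` rotates about ``axis`` (its vector part is parallel to it);
    ``swing`` re-points the limb axis and has no rotation component about it.
    """

    swing: np.ndarray
    twist: np.ndarray
    axis: np.ndarray


def swing_twist_decompose(q_rel: np.ndarray, axis=(1.0, 0.0, 0.0)) -> SwingTwist:
    """Decompose a relative rotation into twist about ``axis`` then swing.

    The twist is the normalized ``[w, (v·u)u]`` with v the vector part of
    ``q_rel`` projected onto the unit axis u; the swing is
    ``q_rel ⊗ twist⁻¹``.  In the singular case of a pure 180° rotation about
    an axis orthogonal to u the projection vanishes; the twist is then taken
    as the identity and the swing as ``q_rel`` itself.
    """
    q_rel = _check_finite(q_rel)
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    w = q_rel[..., :1]
    v = q_rel[..., 1:]
    proj = np.sum(v * u, axis=-1, keepdims=True) * u
    raw_twist = np.concatenate([w, proj], axis=-1)
    n = np.linalg.norm(raw_twist, axis=-1, keepdims=True)
    degenerate = n < _TWIST_EPS
    safe_n = np.where(degenerate, 1.0, n)
    twist = np.where(degenerate, IDENTITY, raw_twist / safe_n)
    swing = hamilton_product(q_rel, quat_inverse(twist))
    return SwingTwist(swing=swing, twist=twist, axis=u)


def geodesic_error_deg(q_hat: np.ndarray, q_gt: np.ndarray) -> np.ndarray:
    """Geodesic angular error on SO(3) in degrees, in [0°, 180°].

    Computed as ``2·arccos(|w(Δq)|)`` with Δq = q_hat ⊗ q_gt⁻¹.  Taking the
    absolute scalar part respects the double cover: antipodal quaternions
    (identical rotations) give exactly 0°.
    """
    dq = hamilton_product(q_hat, quat_inverse(q_gt))
    w = np.clip(np.abs(dq[..., 0]), 0.0, 1.0)
    return np.degrees(2.0 * np.arccos(w))


def avatar_calibration(
    q_sensor_tpose: np.ndarray, q_avatar_tpose: np.ndarray, q_raw: np.ndarray
) -> np.ndarray:
    """Retarget a raw sensor orientation onto an avatar joint frame.

    The offset ``q_calib = q_sensor_tpose⁻¹ ⊗ q_avatar_tpose`` is captured
    once during a simultaneous T-pose; at runtime ``q_joint = q_raw ⊗
    q_calib``, so at the T-pose instant the avatar joint reproduces its
    reference orientation exactly.
    """
    q_calib = hamilton_product(quat_inverse(q_sensor_tpose), q_avatar_tpose)
    return hamilton_product(q_raw, q_calib)


def quat_log(q: np.ndarray) -> np.ndarray:
    """Logarithm map S³ → R³: rotation vector (axis × angle, radians).

    Near the identity the sin(θ/2)/θ ratio is evaluated by series expansion,
    so there is no division by a vanishing vector norm.
    """
    q = _check_finite(q)
    q = canonicalize(q)  # log of a rotation: pick the short arc
    w = np.clip(q[..., :1], -1.0, 1.0)
    v = q[..., 1:]
    vn = np.linalg.norm(v, axis=-1, keepdims=True)
    half = np.arctan2(vn, w)  # θ/2 in [0, π/2] after canonicalization
    # scale = θ / ||v|| = 2·half / sin(half); series for small half
    small = vn < 1e-8
    safe_vn = np.where(small, 1.0, vn)
    scale = np.where(small, 2.0 / np.clip(w, 1e-12, None), 2.0 * half / safe_vn)
    return v * scale


def quat_exp(v: np.ndarray) -> np.ndarray:
    """Exponential map R³ → S³ of a rotation vector (axis × angle)."""
    v = _check_finite(np.asarray(v, dtype=float), "rotation vector")
    theta = np.linalg.norm(v, axis=-1, keepdims=True)
    half = 0.5 * theta
    small = theta < 1e-8
    safe_theta = np.where(small, 1.0, theta)
    # sin(θ/2)/θ → 1/2 − θ²/48 as θ → 0
    k = np.where(small, 0.5 - theta**2 / 48.0, np.sin(half) / safe_theta)
    return np.concatenate([np.cos(half), v * k], axis=-1)


def from_axis_angle(axis, angle_rad) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_rad`` about ``axis``."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    angle = np.asarray(angle_rad, dtype=float)[..., None]
    return np.concatenate(
        [np.cos(angle / 2.0), u * np.sin(angle / 2.0)], axis=-1
    )


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate 3-vectors by unit quaternions: q ⊗ [0,v] ⊗ q⁻¹."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    pv = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    return hamilton_product(hamilton_product(q, pv), quat_inverse(q))[..., 1:]


def random_unit(rng: np.random.Generator, shape=()) -> np.ndarray:
    """Uniform random unit quaternions (Haar measure on SO(3) up to sign)."""
    shape = (shape,) if isinstance(shape, int) else tuple(shape)
    q = rng.standard_normal(shape + (4,))
    return q / np.linalg.norm(q, axis=-1, keepdims=True)
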