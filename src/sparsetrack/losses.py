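"""Physics-informed multi-task objective.

L_MTL = λ_q·L_quat + λ_ω·L_vel + λ_a·L_acc with the critically damped
defaults λ_q=1.0, λ_ω=0.1, λ_a=0.01.  The orientation term is the
antipodally invariant cosine loss 1 − |q̂·q| on the unit-quaternion
hypersphere; the velocity and acceleration terms are Smooth-L1 (Huber,
knee at 1) penalties that keep small errors quadratic while bounding the
influence of high-kurtosis inertial spikes.  The velocity term is the
stationarity soft constraint driving hard-negative mining: it penalizes
spurious proximal angular velocity without the drift-inducing hardness of a
zero-velocity equality constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LossWeights:
    lambda_q: float = 1.0
    lambda_vel: float = 0.1
    lambda_acc: float = 0.01

    def __post_init__(self):
        if min(self.lambda_q, self.lambda_vel, self.lambda_acc) < 0:
            raise ValueError("loss weights must be non-negative")


def quat_cosine_loss(q_hat: np.ndarray, q_gt: np.ndarray):
    """Mean of 1 − |q̂·q_gt| over all joints and samples; in [0, 1].

    Returns ``(loss, grad_wrt_q_hat)``.  Both arguments are unit
    quaternions of shape (..., 4); the absolute value makes the loss (and
    its gradient) invariant to the sign of either argument.
    """
    dot = np.sum(q_hat * q_gt, axis=-1)
    n = dot.size
    loss = float(np.mean(1.0 - np.abs(dot)))
    grad = -np.sign(dot)[..., None] * q_gt / n
    return loss, grad


def _huber(e: np.ndarray):
    """Elementwise Smooth-L1 with knee 1 and its derivative.

    At |e| = 1 both branches agree (0.5); the linear branch is used.
    """
    ae = np.abs(e)
    quad = ae < 1.0
    val = np.where(quad, 0.5 * e * e, ae - 0.5)
    dval = np.where(quad, e, np.sign(e))
    return val, dval


def huber_velocity_loss(w_hat: np.ndarray, w_gt: np.ndarray):
    """Mean Smooth-L1 over the 3J angular-velocity components.

    Returns ``(loss, grad_wrt_w_hat)``.
    """
    val, dval = _huber(w_hat - w_gt)
    return float(val.mean()), dval / val.size


def huber_acceleration_loss(a_hat: np.ndarray, a_gt: np.ndarray):
    """Identical contract to :func:`huber_velocity_loss`, on accelerations."""
    val, dval = _huber(a_hat - a_gt)
    return float(val.mean()), dval / val.size


def total_loss(
    pred: np.ndarray,
    target: np.ndarray,
    weights: LossWeights = LossWeights(),
    hardneg_mask: np.ndarray | None = None,
    vel_loss_scope: str = "all",
):
    """Weighted multi-task loss on (B, 4, 10) prediction/target blocks.

    Block layout per joint: swing quaternion [0:4], ω [4:7], a [7:10].
    Returns ``(loss, breakdown, grad)`` where ``breakdown`` holds the three
    unweighted terms and ``grad`` is ∂loss/∂pred with the quaternion part
    taken w.r.t. the normalized swing.

    ``vel_loss_scope='hardneg'`` restricts the velocity term to the samples
    flagged in ``hardneg_mask`` (the alternative reading of the
    stationarity constraint); the default applies it to every sample.
    """
    if vel_loss_scope not in ("all", "hardneg"):
        raise ValueError(f"bad vel_loss_scope {vel_loss_scope!r}")
    grad = np.zeros_like(pred)
    lq, gq = quat_cosine_loss(pred[..., :4], target[..., :4])
    grad[..., :4] = weights.lambda_q * gq

    if vel_loss_scope == "hardneg" and hardneg_mask is not None:
        mask = np.asarray(hardneg_mask, dtype=bool)
        if mask.any():
            lv, gv = huber_velocity_loss(pred[mask, :, 4:7], target[mask, :, 4:7])
            grad[mask, :, 4:7] = weights.lambda_vel * gv
        else:
            lv = 0.0
    else:
        lv, gv = huber_velocity_loss(pred[..., 4:7], target[..., 4:7])
        grad[..., 4:7] = weights.lambda_vel * gv

    la, ga = huber_acceleration_loss(pred[..., 7:10], target[..., 7:10])
    grad[..., 7:10] = weights.lambda_acc * ga

    loss = weights.lambda_q * lq + weights.lambda_vel * lv + weights.lambda_acc * la
    breakdown = {"quat": lq, "vel": lv, "acc": la}
    return float(loss), breakdown, grad
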