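"""Root-relative evaluation suite.

All metrics are computed in the body-centric reference frame (BCRF) rooted
at the sternum, so they measure articulation quality only, never global
translation drift.  Positions are kept in centimeters for MPJPE/PCK and
converted to meters for the temporal smoothness error (TSE), which is
reported in m/s².  Standard deviations use frame-wise aggregation: the
per-frame mean over joints forms the series whose population σ is reported
(joint errors within a frame are kinematically coupled, not IID).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import quat
from .features import JOINTS


@dataclass(frozen=True)
class Segment:
    parent: str | None
    direction: tuple  # unit bone direction in the parent-aligned T-pose frame
    length_cm: float


_HIP_DIR_L = (0.5, -np.sqrt(3) / 2, 0.0)
_HIP_DIR_R = (-0.5, -np.sqrt(3) / 2, 0.0)


@dataclass(frozen=True)
class Skeleton:
    """Segment topology rooted at the sternum, lengths in cm.

    The canonical T-pose has arms extended laterally along ±x and legs
    hanging along −y; z points forward.  Default lengths: humerus 30,
    forearm 25, thigh 40, shank 40, shoulder offset 20, hip offset 10.
    """

    segments: dict = field(
        default_factory=lambda: {
            "left_shoulder": Segment("sternum", (1, 0, 0), 20.0),
            "right_shoulder": Segment("sternum", (-1, 0, 0), 20.0),
            "left_upper_arm": Segment("left_shoulder", (1, 0, 0), 30.0),
            "right_upper_arm": Segment("right_shoulder", (-1, 0, 0), 30.0),
            "left_forearm": Segment("left_upper_arm", (1, 0, 0), 25.0),
            "right_forearm": Segment("right_upper_arm", (-1, 0, 0), 25.0),
            "left_hip": Segment("sternum", _HIP_DIR_L, 10.0),
            "right_hip": Segment("sternum", _HIP_DIR_R, 10.0),
            "left_upper_leg": Segment("left_hip", (0, -1, 0), 40.0),
            "right_upper_leg": Segment("right_hip", (0, -1, 0), 40.0),
            "left_shank": Segment("left_upper_leg", (0, -1, 0), 40.0),
            "right_shank": Segment("right_upper_leg", (0, -1, 0), 40.0),
        }
    )

    def __post_init__(self):
        for name, seg in self.segments.items():
            if seg.length_cm <= 0:
                raise ValueError(f"segment {name} has non-positive length")
            if seg.parent is not None and seg.parent != "sternum" and seg.parent not in self.segments:
                raise ValueError(f"segment {name} has unknown parent {seg.parent}")

    def topo_order(self) -> list:
        order, seen = [], set()

        def visit(name):
            if name in seen or name == "sternum":
                return
            parent = self.segments[name].parent
            if parent != "sternum":
                visit(parent)
            seen.add(name)
            order.append(name)

        for name in self.segments:
            visit(name)
        return order

    def anchor(self, joint: str) -> np.ndarray:
        """T-pose position (cm) of the proximal end of ``joint``."""
        seg = self.segments[joint]
        if seg.parent == "sternum" or seg.parent is None:
            return np.zeros(3)
        p = self.segments[seg.parent]
        return self.anchor(seg.parent) + np.asarray(p.direction, float) * p.length_cm


def forward_kinematics(skeleton: Skeleton, local_rotations: dict) -> dict:
    """Compose per-segment local rotations from the sternum root outward.

    ``local_rotations`` maps every segment name to a (..., 4) quaternion
    rotating the segment relative to its parent; the returned dict maps
    segment names to the (..., 3) positions (cm) of their distal ends,
    sternum at the origin.  A missing segment raises ``KeyError``.
    """
    missing = set(skeleton.segments) - set(local_rotations)
    if missing:
        raise KeyError(f"missing rotations for segments: {sorted(missing)}")
    global_q: dict[str, np.ndarray] = {}
    positions: dict[str, np.ndarray] = {}
    for name in skeleton.topo_order():
        seg = skeleton.segments[name]
        q_local = np.asarray(local_rotations[name], dtype=float)
        if seg.parent == "sternum" or seg.parent is None:
            q_g = q_local
            base = np.zeros(3)
        else:
            q_g = quat.hamilton_product(global_q[seg.parent], q_local)
            base = positions[seg.parent]
        bone = np.asarray(seg.direction, float) * seg.length_cm
        positions[name] = base + quat.rotate_vector(q_g, np.broadcast_to(bone, q_g.shape[:-1] + (3,)))
        global_q[name] = q_g
    return positions


# bone length rotated by each predicted joint's swing
_SWING_BONE_CM = {"left_upper_arm": 30.0, "right_upper_arm": 30.0,
                  "left_upper_leg": 40.0, "right_upper_leg": 40.0}


def positions_from_swing(swing: np.ndarray, skeleton: Skeleton | None = None,
                         joints: tuple = JOINTS) -> np.ndarray:
    """Map (T, J, 4) swing rotations to root-relative joint positions (cm).

    The swing rotation re-points the proximal bone axis u = [1,0,0] (the
    anatomical twist axis, along which axial twist has no positional
    effect), so the distal end of each proximal segment is
    ``anchor + L·R(q_swing)·u``.  Prediction and ground truth are evaluated
    on the same canonical skeleton (retargeting), so positional error
    reflects articulation only.
    """
    skeleton = skeleton or Skeleton()
    u = np.array([1.0, 0.0, 0.0])
    out = np.empty(swing.shape[:-1] + (3,))
    for j, name in enumerate(joints):
        anchor = skeleton.anchor(name)
        L = _SWING_BONE_CM[name]
        out[..., j, :] = anchor + L * quat.rotate_vector(swing[..., j, :], u)
    return out


def mpjpe(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean per-joint position error (cm) over all joint-frame pairs."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    return float(np.linalg.norm(pred - gt, axis=-1).mean())


def position_errors(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """(T, J) Euclidean errors in cm."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    return np.linalg.norm(pred - gt, axis=-1)


def pck(errors: np.ndarray, threshold_cm: float) -> float:
    """Percentage of joint-frame pairs with error strictly below the
    threshold."""
    if threshold_cm <= 0:
        raise ValueError("PCK threshold must be positive")
    e = np.asarray(errors, dtype=float)
    return float(100.0 * np.mean(e < threshold_cm))


def pck_auc(errors: np.ndarray, max_cm: float = 15.0) -> float:
    """PCK integrated over thresholds 0..15 cm, normalized to [0, 1].

    The exact integral of the strict-threshold PCK curve equals the mean of
    the clipped-error survival function, 1 − E[min(e, 15)]/15, so a perfect
    predictor scores 1.0 and errors beyond 15 cm score 0.
    """
    e = np.asarray(errors, dtype=float)
    return float(np.mean(1.0 - np.minimum(e, max_cm) / max_cm))


def tse(pred_cm: np.ndarray, gt_cm: np.ndarray, dt: float = 1.0 / 60.0) -> float:
    """Temporal smoothness error (m/s²): mean norm of the difference of
    discrete second derivatives of joint position, boundary frames
    excluded.  Inputs are (T, J, 3) in cm and are converted to meters."""
    if pred_cm.shape != gt_cm.shape:
        raise ValueError("shape mismatch")
    if pred_cm.shape[0] < 3:
        raise ValueError("TSE needs at least 3 frames")
    p = np.asarray(pred_cm, float) / 100.0
    g = np.asarray(gt_cm, float) / 100.0
    ap = (p[2:] - 2 * p[1:-1] + p[:-2]) / dt**2
    ag = (g[2:] - 2 * g[1:-1] + g[:-2]) / dt**2
    return float(np.linalg.norm(ap - ag, axis=-1).mean())


def tse_per_frame(pred_cm: np.ndarray, gt_cm: np.ndarray, dt: float = 1.0 / 60.0) -> np.ndarray:
    """(T−2,) per-frame TSE series (mean over joints)."""
    p = np.asarray(pred_cm, float) / 100.0
    g = np.asarray(gt_cm, float) / 100.0
    ap = (p[2:] - 2 * p[1:-1] + p[:-2]) / dt**2
    ag = (g[2:] - 2 * g[1:-1] + g[:-2]) / dt**2
    return np.linalg.norm(ap - ag, axis=-1).mean(axis=-1)


def mae_deg(pred_q: np.ndarray, gt_q: np.ndarray) -> float:
    """Mean geodesic angular error in degrees over joints × frames."""
    return float(quat.geodesic_error_deg(pred_q, gt_q).mean())


def framewise_stats(series: np.ndarray):
    """(mean, population σ, CV) of a per-frame metric series."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("empty metric series")
    mean = float(s.mean())
    sigma = float(s.std())
    cv = sigma / mean if mean != 0 else 0.0
    return mean, sigma, cv


@dataclass
class MetricsReport:
    """Evaluation summary mirroring the standard report columns."""

    mae_deg: float
    sigma_mae_deg: float
    mpjpe_cm: float
    sigma_mpjpe_cm: float
    pck5_pct: float
    pck10_pct: float
    pck_auc: float
    tse_ms2: float
    sigma_tse_ms2: float
    per_joint: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "MAE_deg": self.mae_deg, "sigma_MAE_deg": self.sigma_mae_deg,
            "MPJPE_cm": self.mpjpe_cm, "sigma_MPJPE_cm": self.sigma_mpjpe_cm,
            "PCK@5_pct": self.pck5_pct, "PCK@10_pct": self.pck10_pct,
            "PCK_AUC": self.pck_auc,
            "TSE_ms2": self.tse_ms2, "sigma_TSE_ms2": self.sigma_tse_ms2,
            "per_joint": self.per_joint,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "MetricsReport":
        d = json.loads(Path(path).read_text())
        return cls(
            mae_deg=d["MAE_deg"], sigma_mae_deg=d["sigma_MAE_deg"],
            mpjpe_cm=d["MPJPE_cm"], sigma_mpjpe_cm=d["sigma_MPJPE_cm"],
            pck5_pct=d["PCK@5_pct"], pck10_pct=d["PCK@10_pct"],
            pck_auc=d["PCK_AUC"], tse_ms2=d["TSE_ms2"],
            sigma_tse_ms2=d["sigma_TSE_ms2"], per_joint=d.get("per_joint", {}),
        )

    def table(self) -> str:
        head = f"{'MAE(°)':>8} {'σMAE':>6} {'MPJPE(cm)':>10} {'σMPJPE':>7} " \
               f"{'PCK@5(%)':>9} {'PCK@10(%)':>10} {'PCK-AUC':>8} {'TSE(m/s²)':>10} {'σTSE':>6}"
        row = f"{self.mae_deg:8.2f} {self.sigma_mae_deg:6.2f} {self.mpjpe_cm:10.2f} " \
              f"{self.sigma_mpjpe_cm:7.2f} {self.pck5_pct:9.1f} {self.pck10_pct:10.1f} " \
              f"{self.pck_auc:8.3f} {self.tse_ms2:10.3f} {self.sigma_tse_ms2:6.3f}"
        return head + "\n" + row


def compute_report(pred_swing: np.ndarray, gt_swing: np.ndarray,
                   skeleton: Skeleton | None = None, dt: float = 1.0 / 60.0,
                   joints: tuple = JOINTS) -> MetricsReport:
    """Full report from (T, J, 4) predicted and ground-truth swing series.

    Positions come from the canonical-skeleton swing map; σ columns are
    frame-wise (per-frame mean over joints, population σ over frames).
    """
    skeleton = skeleton or Skeleton()
    pred_p = positions_from_swing(pred_swing, skeleton, joints)
    gt_p = positions_from_swing(gt_swing, skeleton, joints)
    errs = position_errors(pred_p, gt_p)  # (T, J)
    ang = quat.geodesic_error_deg(pred_swing, gt_swing)  # (T, J)

    mae_mean, mae_sigma, _ = framewise_stats(ang.mean(axis=1))
    mp_mean, mp_sigma, _ = framewise_stats(errs.mean(axis=1))
    if pred_p.shape[0] >= 3:
        tse_series = tse_per_frame(pred_p, gt_p, dt)
        tse_mean, tse_sigma, _ = framewise_stats(tse_series)
    else:
        tse_mean = tse_sigma = float("nan")

    per_joint = {
        name: {
            "MAE_deg": float(ang[:, j].mean()),
            "MPJPE_cm": float(errs[:, j].mean()),
        }
        for j, name in enumerate(joints)
    }
    return MetricsReport(
        mae_deg=mae_mean, sigma_mae_deg=mae_sigma,
        mpjpe_cm=mp_mean, sigma_mpjpe_cm=mp_sigma,
        pck5_pct=pck(errs, 5.0), pck10_pct=pck(errs, 10.0),
        pck_auc=pck_auc(errs),
        tse_ms2=tse_mean, sigma_tse_ms2=tse_sigma,
        per_joint=per_joint,
    )
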