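"""Training, evaluation, and real-time stream emulation.

The public surface follows the model/results idiom: build a
:class:`SparseTrackModel` from a dataset of simulated (or recorded)
sessions, call :meth:`~SparseTrackModel.fit`, and work with the returned
:class:`SparseTrackResults` — prediction, streaming inference, metric
reports, post-processing ablations, noise sweeps, checkpointing and a
``summary()`` table all hang off the results object.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import asdict, dataclass, field

import numpy as np

from . import features as F
from . import metrics as M
from . import postprocess, synthkin
from .losses import LossWeights, total_loss
from .model import ModelConfig, TransformerRegressor


@dataclass
class RunConfig:
    """Optimization schedule and mixing configuration.

    Defaults mirror the reference training recipe: AdamW at a fixed
    1e−4 learning rate, batch 64, up to 25 epochs with early stopping
    (patience 10) on the validation multi-task loss, run seed 42, window
    L = 120, hard-negative mixing ratio r = 0.1.
    """

    lr: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 64
    epochs: int = 25
    patience: int = 10
    seed: int = 42
    L: int = 120
    stride: int = 30
    r: float = 0.1
    weights: LossWeights = field(default_factory=LossWeights)
    vel_loss_scope: str = "all"

    def __post_init__(self):
        for name in ("lr", "batch_size", "epochs", "patience", "L", "stride"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class Session:
    """One recorded or simulated file: stream + supervision + label."""

    stream: F.SensorStream
    gt: synthkin.GroundTruth
    label: str  # "adl" or "hard_negative:<task>"

    @property
    def is_hard_negative(self) -> bool:
        return self.label.startswith("hard_negative")


def simulate_sessions(
    n_adl: int, n_hard: int, duration_s: float, seed: int,
    sim_config: synthkin.SimConfig | None = None,
) -> list[Session]:
    """Generate a deterministic pool of ADL and hard-negative sessions."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_adl + n_hard)
    out = []
    for i in range(n_adl):
        sub = int(child[i].generate_state(1)[0] % (2**31))
        script = synthkin.generate_adl_motion(duration_s, seed=sub)
        cfg = sim_config or synthkin.SimConfig(seed=sub)
        stream, gt = synthkin.simulate_imu_stream(script, config=cfg)
        out.append(Session(stream, gt, "adl"))
    tasks = synthkin.ISOLATION_TASKS
    for i in range(n_hard):
        sub = int(child[n_adl + i].generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub)
        task = tasks[i % len(tasks)]
        freq = rng.uniform(0.5, 2.0)
        script = synthkin.generate_isolation_task(task, freq, seed=sub, duration_s=duration_s)
        cfg = sim_config or synthkin.SimConfig(seed=sub)
        stream, gt = synthkin.simulate_imu_stream(script, config=cfg)
        out.append(Session(stream, gt, script.label))
    return out


@dataclass
class MotionDataset:
    """Windowed train/val/test pools with frozen training statistics."""

    norm_stats: F.NormStats
    target_stats: F.TargetStats
    train_adl_X: np.ndarray
    train_adl_y: np.ndarray
    train_hard_X: np.ndarray
    train_hard_y: np.ndarray
    val_X: np.ndarray
    val_y: np.ndarray
    test_sessions: list
    L: int = 120
    stride: int = 30

    @classmethod
    def from_sessions(cls, sessions: list[Session], L: int = 120, stride: int = 30,
                      split=(0.8, 0.1, 0.1), seed: int = 42) -> "MotionDataset":
        """Partition by file (80/10/10 by default), freeze normalization
        statistics on the training partition, and window every file."""
        rng = np.random.default_rng(seed)
        adl = [s for s in sessions if not s.is_hard_negative]
        hard = [s for s in sessions if s.is_hard_negative]

        def partition(pool):
            idx = rng.permutation(len(pool))
            n_val = max(1, int(round(split[1] * len(pool)))) if len(pool) > 2 else 0
            n_test = max(1, int(round(split[2] * len(pool)))) if len(pool) > 2 else 0
            test = [pool[i] for i in idx[:n_test]]
            val = [pool[i] for i in idx[n_test:n_test + n_val]]
            train = [pool[i] for i in idx[n_test + n_val:]]
            return train, val, test

        adl_tr, adl_va, adl_te = partition(adl)
        hard_tr, hard_va, hard_te = partition(hard)
        return cls.from_partitioned(
            adl_tr + hard_tr, adl_va + hard_va, adl_te + hard_te, L=L, stride=stride
        )

    @classmethod
    def from_partitioned(cls, train: list, val: list, test: list,
                         L: int = 120, stride: int = 30) -> "MotionDataset":
        """Build pools from an externally fixed file partition (e.g., a
        dataset manifest)."""
        adl_tr = [s for s in train if not s.is_hard_negative]
        hard_tr = [s for s in train if s.is_hard_negative]
        if not adl_tr:
            raise ValueError("training partition is empty")
        norm_stats = F.compute_norm_stats([s.stream for s in adl_tr + hard_tr])
        omega = np.concatenate([s.gt.omega for s in adl_tr + hard_tr])
        acc = np.concatenate([s.gt.acc for s in adl_tr + hard_tr])
        adl_va = [s for s in val if not s.is_hard_negative]
        hard_va = [s for s in val if s.is_hard_negative]
        adl_te = [s for s in test if not s.is_hard_negative]
        hard_te = [s for s in test if s.is_hard_negative]
        target_stats = F.compute_target_stats(omega, acc)

        def windows(pool):
            Xs, ys = [], []
            for s in pool:
                feats = F.assemble_features(s.stream, norm_stats)
                tgt = F.make_training_target(
                    s.gt.q_proximal, s.gt.q_distal, s.gt.omega, s.gt.acc, target_stats
                )
                X, y = F.sliding_windows(feats, tgt, L=L, stride=stride)
                if len(X):
                    Xs.append(X)
                    ys.append(y)
            if not Xs:
                return (np.empty((0, L, F.FRAME_DIM)), np.empty((0, 4, 10)))
            return np.concatenate(Xs), np.concatenate(ys)

        tr_a = windows(adl_tr)
        tr_h = windows(hard_tr)
        va = windows(adl_va + hard_va)
        return cls(
            norm_stats=norm_stats, target_stats=target_stats,
            train_adl_X=tr_a[0], train_adl_y=tr_a[1],
            train_hard_X=tr_h[0], train_hard_y=tr_h[1],
            val_X=va[0], val_y=va[1],
            test_sessions=adl_te + hard_te, L=L, stride=stride,
        )


class SparseTrackModel:
    """Sparse-IMU proximal-joint regressor bound to a dataset.

    ``fit()`` trains the attention network with the physics-informed
    multi-task loss and hard-negative batch mixing and returns a
    :class:`SparseTrackResults`.
    """

    def __init__(self, dataset: MotionDataset,
                 model_config: ModelConfig | None = None,
                 run_config: RunConfig | None = None):
        self.dataset = dataset
        self.run_config = run_config or RunConfig()
        self.model_config = model_config or ModelConfig(L=self.run_config.L)
        if self.model_config.L != dataset.L:
            raise ValueError("model window length differs from dataset windows")

    @classmethod
    def from_sessions(cls, sessions, model_config=None, run_config=None):
        rc = run_config or RunConfig()
        ds = MotionDataset.from_sessions(sessions, L=rc.L, stride=rc.stride, seed=rc.seed)
        return cls(ds, model_config=model_config, run_config=rc)

    def _val_loss(self, net) -> float:
        ds, rc = self.dataset, self.run_config
        if not len(ds.val_X):
            return float("nan")
        losses, n = [], 0
        for i in range(0, len(ds.val_X), 64):
            X, y = ds.val_X[i : i + 64], ds.val_y[i : i + 64]
            pred = net.forward(X)
            l, _, _ = total_loss(pred, y, rc.weights)
            losses.append(l * len(X))
            n += len(X)
        return float(np.sum(losses) / n)

    def fit(self, verbose: bool = False) -> "SparseTrackResults":
        from .nn import AdamW

        ds, rc = self.dataset, self.run_config
        net = TransformerRegressor(self.model_config, seed=rc.seed)
        opt = AdamW(net.params, lr=rc.lr, weight_decay=rc.weight_decay)
        drop_rng = np.random.default_rng(np.random.SeedSequence([rc.seed, 0xD0]))
        r = rc.r if len(ds.train_hard_X) else 0.0
        history = {"train_loss": [], "val_loss": [], "breakdown": []}
        best = {"val": np.inf, "params": None, "epoch": -1}
        since_best = 0
        for epoch in range(rc.epochs):
            batch_losses, bds = [], []
            for adl_idx, hard_idx in F.mix_batches(
                len(ds.train_adl_X), len(ds.train_hard_X),
                batch_size=rc.batch_size, r=r, seed=rc.seed + epoch,
            ):
                X = np.concatenate([ds.train_adl_X[adl_idx], ds.train_hard_X[hard_idx]]) \
                    if len(hard_idx) else ds.train_adl_X[adl_idx]
                y = np.concatenate([ds.train_adl_y[adl_idx], ds.train_hard_y[hard_idx]]) \
                    if len(hard_idx) else ds.train_adl_y[adl_idx]
                mask = np.zeros(len(X), dtype=bool)
                mask[len(adl_idx):] = True
                pred = net.forward(X, dropout_rng=drop_rng)
                loss, bd, grad = total_loss(
                    pred, y, rc.weights, hardneg_mask=mask,
                    vel_loss_scope=rc.vel_loss_scope,
                )
                grads = net.backward(grad)
                opt.step(net.params, grads)
                batch_losses.append(loss)
                bds.append(bd)
            if not batch_losses:
                raise ValueError(
                    "training pool smaller than one batch; reduce batch_size or add data"
                )
            train_loss = float(np.mean(batch_losses))
            val_loss = self._val_loss(net)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            history["breakdown"].append(
                {k: float(np.mean([b[k] for b in bds])) for k in ("quat", "vel", "acc")}
                if bds else {}
            )
            if verbose:
                print(f"epoch {epoch}: train {train_loss:.5f}  val {val_loss:.5f}")
            crit = val_loss if np.isfinite(val_loss) else train_loss
            if crit < best["val"]:
                best = {"val": crit,
                        "params": {k: v.copy() for k, v in net.params.items()},
                        "epoch": epoch}
                since_best = 0
            else:
                since_best += 1
                if since_best >= rc.patience:
                    break
        if best["params"] is not None:
            net.params = best["params"]
        return SparseTrackResults(
            net=net, history=history, run_config=rc,
            norm_stats=ds.norm_stats, target_stats=ds.target_stats,
            best_epoch=best["epoch"],
        )


class SparseTrackResults:
    """Fitted estimator state: best weights, training history, frozen
    normalization statistics, and every downstream operation."""

    def __init__(self, net: TransformerRegressor, history: dict, run_config: RunConfig,
                 norm_stats: F.NormStats, target_stats: F.TargetStats, best_epoch: int):
        self.net = net
        self.history = history
        self.run_config = run_config
        self.norm_stats = norm_stats
        self.target_stats = target_stats
        self.best_epoch = best_epoch

    # -- prediction ---------------------------------------------------------

    def predict_windows(self, X: np.ndarray, batch: int = 64) -> np.ndarray:
        """(N, L, 50) windows → (N, 4, 10) joint blocks, eval mode."""
        return np.concatenate(
            [self.net.forward(X[i : i + batch]) for i in range(0, len(X), batch)]
        ) if len(X) else np.empty((0, 4, 10))

    def predict_session(self, stream: F.SensorStream, stride: int = 1) -> np.ndarray:
        """Batch-mode sliding-window prediction over a full stream."""
        feats = F.assemble_features(stream, self.norm_stats)
        X = F.sliding_windows(feats, None, L=self.run_config.L, stride=stride)
        return self.predict_windows(X)

    def predict_stream(self, stream: F.SensorStream):
        """FIFO streaming inference: no output until L frames are buffered,
        thereafter one prediction per incoming frame from past frames only.
        Frame-for-frame identical to :meth:`predict_session` at stride 1 on
        clean streams; a non-finite sensor frame (dropout) holds the last
        valid frame with a warning instead of corrupting the window.
        """
        import warnings

        L = self.run_config.L
        bad = F._bad_frame_mask(stream)
        if bad.any():
            good = np.flatnonzero(~bad)
            if good.size == 0:
                return np.empty((0, 4, 10))
            warnings.warn(
                f"{int(bad.sum())} non-finite sensor frames; holding last pose",
                stacklevel=2,
            )
            stream = stream.copy()
            fill = np.maximum.accumulate(np.where(~bad, np.arange(len(stream)), -1))
            fill[fill < 0] = good[0]
            stream.quat = stream.quat[fill]
            stream.gyro = stream.gyro[fill]
            stream.acc = stream.acc[fill]
        feats = F.assemble_features(stream, self.norm_stats)
        buf: deque = deque(maxlen=L)
        preds = []
        for t in range(len(stream)):
            buf.append(feats[t])
            if len(buf) == L:
                X = np.asarray(buf)[None]
                preds.append(self.net.forward(X)[0])
        return np.asarray(preds) if preds else np.empty((0, 4, 10))

    def denormalized_omega(self, pred: np.ndarray) -> np.ndarray:
        """Map predicted normalized ω blocks back to rad/s."""
        mu = self.target_stats.mu[:, 0, None]
        sigma = self.target_stats.sigma[:, 0, None]
        return pred[..., 4:7] * (sigma + F.EPS) + mu

    # -- evaluation ---------------------------------------------------------

    def evaluate_session(self, session: Session, apply_post: bool = True,
                         stride: int = 1) -> M.MetricsReport:
        """Metric report over one held-out session, predictions aligned to
        the final frame of each window; post-processing (joint-limit clamp +
        MEKF) can be disabled for ablation."""
        pred = self.predict_session(session.stream, stride=stride)
        L = self.run_config.L
        idx = np.arange(len(pred)) * stride + L - 1
        gt_swing = session.gt.swing[idx]
        pred_swing = pred[..., :4]
        if apply_post:
            pred_swing = postprocess.apply_postprocessing(pred_swing, F.JOINTS)
        return M.compute_report(pred_swing, gt_swing)

    def evaluate(self, sessions: list, apply_post: bool = True, stride: int = 2) -> M.MetricsReport:
        """Pooled frame-wise report over several sessions."""
        preds, gts = [], []
        L = self.run_config.L
        for s in sessions:
            pred = self.predict_session(s.stream, stride=stride)
            idx = np.arange(len(pred)) * stride + L - 1
            swing = pred[..., :4]
            if apply_post:
                swing = postprocess.apply_postprocessing(swing, F.JOINTS)
            preds.append(swing)
            gts.append(s.gt.swing[idx])
        return M.compute_report(np.concatenate(preds), np.concatenate(gts))

    def noise_sweep(self, session: Session, sigmas, seed: int = 42, stride: int = 2) -> list[dict]:
        """Stress test: inject Gaussian noise into the normalized inertial
        feature channels at each σ and report MPJPE/TSE degradation
        relative to the clean run."""
        L = self.run_config.L
        feats_clean = F.assemble_features(session.stream, self.norm_stats)
        rows = []
        base_mpjpe = None
        for sigma in sigmas:
            feats = synthkin.noise_on_features(feats_clean, sigma, seed)
            X = F.sliding_windows(feats, None, L=L, stride=stride)
            pred = self.predict_windows(X)
            idx = np.arange(len(pred)) * stride + L - 1
            swing = postprocess.apply_postprocessing(pred[..., :4], F.JOINTS)
            rep = M.compute_report(swing, session.gt.swing[idx])
            if base_mpjpe is None:
                base_mpjpe = rep.mpjpe_cm
            rows.append({
                "sigma": float(sigma),
                "MPJPE_cm": rep.mpjpe_cm,
                "TSE_ms2": rep.tse_ms2,
                "degradation_pct": 100.0 * (rep.mpjpe_cm - base_mpjpe) / base_mpjpe,
            })
        return rows

    # -- reporting / persistence --------------------------------------------

    def summary(self) -> str:
        c = self.net.config
        lines = [
            "SparseTrack sparse-IMU proximal-joint regression",
            "=" * 52,
            f"encoder layers      : {c.n_layers}  (d_model={c.d_model}, heads={c.n_heads}, d_ff={c.d_ff})",
            f"window / input / out: L={c.L} frames, {c.d_in} features, {c.d_out} targets",
            f"trainable parameters: {self.net.n_params:,}",
            f"epochs run          : {len(self.history['train_loss'])} (best @ {self.best_epoch})",
        ]
        if self.history["train_loss"]:
            lines.append(f"final train L_MTL   : {self.history['train_loss'][-1]:.5f}")
            vl = self.history["val_loss"][self.best_epoch]
            lines.append(f"best val L_MTL      : {vl:.5f}")
            bd = self.history["breakdown"][-1]
            if bd:
                lines.append(
                    "loss breakdown      : quat {quat:.5f} | vel {vel:.5f} | acc {acc:.5f}".format(**bd)
                )
        return "\n".join(lines)

    def save(self, path) -> None:
        extra = {
            "run_config": {**self.run_config.to_dict(),
                           "weights": asdict(self.run_config.weights)},
            "norm_stats": self.norm_stats.to_dict(),
            "target_stats": self.target_stats.to_dict(),
            "history": self.history,
            "best_epoch": self.best_epoch,
        }
        self.net.save(path, extra=extra)

    @classmethod
    def load(cls, path) -> "SparseTrackResults":
        net, extra = TransformerRegressor.load(path)
        rc_d = dict(extra["run_config"])
        rc_d["weights"] = LossWeights(**rc_d["weights"])
        rc = RunConfig(**rc_d)
        return cls(
            net=net, history=extra["history"], run_config=rc,
            norm_stats=F.NormStats.from_dict(extra["norm_stats"]),
            target_stats=F.TargetStats.from_dict(extra["target_stats"]),
            best_epoch=extra["best_epoch"],
        )


def desk_scale_experiment(
    seed: int = 42,
    n_adl: int = 18,
    n_hard: int = 6,
    duration_s: float = 60.0,
    epochs: int = 6,
    model_config: ModelConfig | None = None,
    eval_stride: int = 4,
    train_contrast: bool = True,
) -> dict:
    """CPU-scale end-to-end study: train the reduced model on synthetic
    motion and measure the physics-informed behaviors.

    Trains the regressor with the standard 10% hard-negative mixing (and,
    when ``train_contrast`` is set, a second model without any injection),
    then evaluates on held-out sessions: pooled metric reports with and
    without post-processing, the constant-T-pose baseline, and the mean
    predicted proximal angular speed on held-out distal-isolation tasks for
    both models.  Everything derives from ``seed``.
    """
    sessions = simulate_sessions(n_adl, n_hard, duration_s, seed)
    ds = MotionDataset.from_sessions(sessions, L=120, stride=30, seed=seed)
    mc = model_config or ModelConfig.reduced(L=ds.L)
    res = SparseTrackModel(ds, mc, RunConfig(epochs=epochs, seed=seed, r=0.1)).fit()
    res_plain = None
    if train_contrast:
        res_plain = SparseTrackModel(ds, mc, RunConfig(epochs=epochs, seed=seed, r=0.0)).fit()

    L = ds.L
    adl_test = [s for s in ds.test_sessions if not s.is_hard_negative] or ds.test_sessions[:1]
    hard_test = [s for s in ds.test_sessions if s.is_hard_negative]

    raw_parts, post_parts, gt_parts = [], [], []
    for s in adl_test:
        pred = res.predict_session(s.stream, stride=eval_stride)
        idx = np.arange(len(pred)) * eval_stride + L - 1
        raw = pred[..., :4]
        raw_parts.append(raw)
        post_parts.append(postprocess.apply_postprocessing(raw, F.JOINTS))
        gt_parts.append(s.gt.swing[idx])
    raw_swing = np.concatenate(raw_parts)
    post_swing = np.concatenate(post_parts)
    gt_swing = np.concatenate(gt_parts)

    report_post = M.compute_report(post_swing, gt_swing)
    report_raw = M.compute_report(raw_swing, gt_swing)
    report_baseline = M.compute_report(tpose_baseline_swing(len(gt_swing)), gt_swing)

    def proximal_speed(results, sessions_):
        speeds = []
        for s in sessions_:
            pred = results.predict_session(s.stream, stride=eval_stride)
            omega = results.denormalized_omega(pred)
            speeds.append(np.linalg.norm(omega, axis=-1).mean())
        return float(np.mean(speeds)) if speeds else float("nan")

    out = {
        "history": res.history,
        "report_post": report_post,
        "report_raw": report_raw,
        "report_baseline": report_baseline,
        "results": res,
        "n_train_windows": int(len(ds.train_adl_X) + len(ds.train_hard_X)),
        "hardneg_speed_with_injection": proximal_speed(res, hard_test),
    }
    if res_plain is not None:
        out["history_plain"] = res_plain.history
        out["hardneg_speed_without_injection"] = proximal_speed(res_plain, hard_test)
    return out


def save_sessions(sessions: list[Session], out_dir, split=(0.8, 0.1, 0.1),
                  seed: int = 42) -> str:
    """Write sessions as stream CSVs + ground-truth sidecars and a manifest
    assigning train/val/test partitions by file.  Returns the manifest path.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = F.Manifest()
    order = rng.permutation(len(sessions))
    n = len(sessions)
    n_test = max(1, int(round(split[2] * n))) if n > 2 else 0
    n_val = max(1, int(round(split[1] * n))) if n > 2 else 0
    parts = {}
    for rank, i in enumerate(order):
        parts[i] = "test" if rank < n_test else ("val" if rank < n_test + n_val else "train")
    for i, s in enumerate(sessions):
        stem = f"session_{i:03d}"
        s.stream.to_csv(out / f"{stem}.csv")
        np.savez(
            out / f"{stem}_gt.npz",
            q_proximal=s.gt.q_proximal, q_distal=s.gt.q_distal,
            swing=s.gt.swing, omega=s.gt.omega, acc=s.gt.acc,
        )
        manifest.add(f"{stem}.csv", s.label, parts.get(i, "train"))
    path = out / "manifest.json"
    manifest.save(path)
    return str(path)


def load_sessions(manifest_path, partition: str | None = None) -> list[Session]:
    """Read sessions back from a manifest directory."""
    from pathlib import Path

    mpath = Path(manifest_path)
    root = mpath.parent
    manifest = F.Manifest.load(mpath)
    out = []
    for e in manifest.files(partition=partition):
        stream = F.SensorStream.from_csv(root / e["path"])
        with np.load(root / (Path(e["path"]).stem + "_gt.npz")) as d:
            gt = synthkin.GroundTruth(
                q_proximal=d["q_proximal"], q_distal=d["q_distal"],
                swing=d["swing"], omega=d["omega"], acc=d["acc"],
            )
        out.append(Session(stream, gt, e["label"]))
    return out


def tpose_baseline_swing(n_frames: int) -> np.ndarray:
    """Constant-T-pose predictor: identity swing for every joint, the
    natural no-information baseline for root-relative evaluation."""
    out = np.zeros((n_frames, 4, 4))
    out[..., 0] = 1.0
    return out
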