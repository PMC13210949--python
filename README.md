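# sparsetrack

Sparse-inertial human motion reconstruction: recover the orientations of
**uninstrumented proximal joints** — both upper arms and both upper legs —
from only **five wearable IMUs** (wrists, ankles, torso) streaming unit
quaternions, angular velocity and linear acceleration at 60 Hz.

The package is aimed at biomechanics and human-movement researchers who want
a fully inspectable, CPU-runnable implementation of the sparse inverse
kinematics pipeline: calibration and swing–twist target reparameterization,
a physics-informed attention regressor, hard-negative batch mixing against
kinematic bleed-through, anatomically constrained multiplicative-Kalman
post-processing, and a root-relative evaluation suite — all exercised
end-to-end on a built-in synthetic kinematic simulator, so no motion-capture
corpus is needed to train, test, or study the method.

## The method

With sensors only on distal segments, a single wrist or ankle orientation is
consistent with a continuum of proximal configurations; the mapping is
recovered from the *temporal history* of the distal signals. A window
**X** ∈ ℝ^(L×50) of L = 120 frames (2.0 s, five sensors × 10 features,
strictly causal) is regressed onto the proximal state at its final frame:

- **Targets.** For each proximal joint, the relative rotation
  q_rel = q_proximal ⊗ q_distal⁻¹ is factored as q_rel = q_swing ⊗ q_twist
  about the anatomical limb axis u = [1,0,0]; only the swing (the limb's
  pointing direction) is supervised, discarding noisy axial twist. The
  40-dim output adds each joint's angular velocity and linear acceleration.
- **Network.** A 6-layer pre-layer-norm Transformer encoder
  (d_model = 256, 8 heads, GELU feed-forward of width 1024, sinusoidal
  positional encoding, ≈4.76 M parameters; a d_model = 64 / 2-layer
  reduction is provided for CPU-scale studies), reading only the last-frame
  latent through four parallel per-joint linear heads. The network and its
  training loop (AdamW) are implemented in NumPy with hand-derived,
  finite-difference-verified backward passes.
- **Loss.** L_MTL = λ_q (1 − |q̂·q|) + λ_ω Huber(ω̂ − ω) + λ_a Huber(â − a)
  with λ_q = 1.0, λ_ω = 0.1, λ_a = 0.01. The cosine term respects the
  quaternion double cover (q ≡ −q); the velocity term is the stationarity
  soft constraint that, together with mixing ≈10% distal-isolation
  "hard negative" sequences (|ω_proximal| < 0.1 rad/s) into every batch,
  teaches the model that frantic distal motion can coexist with a still
  shoulder or hip.
- **Post-processing.** Per-joint Euler-box limit clamping (elbow hinge
  [5°, 150°], shoulder box [−45°, 150°]) followed by a scalar-gain
  multiplicative extended Kalman filter on S³
  (K = (P+σ_p²)/(P+σ_p²+σ_m²), σ_p² = 10⁻⁶, σ_m² = 10⁻³) via the SO(3)
  log/exp maps.
- **Evaluation.** Root-relative (sternum-centred): geodesic MAE (deg),
  MPJPE (cm) through forward kinematics on a canonical skeleton, PCK@5/10,
  PCK-AUC over 0–15 cm, and the temporal smoothness error TSE (m/s²) on
  discrete second derivatives, with frame-wise σ aggregation.

## Worked example

```python
from sparsetrack import (
    ModelConfig, MotionDataset, RunConfig, SparseTrackModel, simulate_sessions,
)

sessions = simulate_sessions(n_adl=8, n_hard=3, duration_s=30.0, seed=42)
dataset = MotionDataset.from_sessions(sessions, L=120, stride=30, seed=42)
model = SparseTrackModel(dataset, ModelConfig.reduced(L=120), RunConfig(epochs=4, seed=42))
results = model.fit()
print(results.summary())
report = results.evaluate(dataset.test_sessions, apply_post=True)
print(report.table())
```

prints

```
SparseTrack sparse-IMU proximal-joint regression
====================================================
encoder layers      : 2  (d_model=64, heads=4, d_ff=256)
window / input / out: L=120 frames, 50 features, 40 targets
trainable parameters: 105,960
epochs run          : 4 (best @ 3)
final train L_MTL   : 0.35919
best val L_MTL      : 0.30680
loss breakdown      : quat 0.26668 | vel 0.83555 | acc 0.89553

  MAE(°)   σMAE  MPJPE(cm)  σMPJPE  PCK@5(%)  PCK@10(%)  PCK-AUC  TSE(m/s²)   σTSE
   58.95  11.87      27.39    4.31       4.8       10.1    0.075     35.407 39.044
```

Four epochs on four minutes of training motion only begin to bend the curves
— the validation multi-task loss has fallen from its initial ≈0.53 to 0.31
and the MPJPE is already well below the ≈40 cm of a constant-T-pose
baseline, but far from converged; the longer study run by the acceptance
script roughly halves these errors, and the reported MPJPE/TSE should be
read against that baseline rather than against production-scale training.

A command-line interface wraps the same facade:

```sh
sparsetrack simulate --n-adl 8 --n-hard 3 --duration 60 --out-dir data/
sparsetrack train --manifest data/manifest.json --out-dir run/
sparsetrack evaluate --checkpoint run/checkpoint.npz --manifest data/manifest.json
sparsetrack infer-stream --checkpoint run/checkpoint.npz --stream data/session_000.csv --out preds.csv
sparsetrack noise-sweep --checkpoint run/checkpoint.npz --manifest data/manifest.json
```

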