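# Methods

## Problem and model

Five body-worn IMUs (left/right wrist, left/right ankle, torso) each
deliver, at 60 Hz, a unit orientation quaternion (w-first, Hamilton
convention), a 3-axis angular velocity in rad/s, and a 3-axis linear
acceleration in m/s². The four proximal joints they do *not* instrument —
upper arms and upper legs — are regressed from a strictly causal sliding
window of L = 120 frames (2.0 s). The window length is treated as a design
constant: long enough to contain preparatory motion that disambiguates the
one-to-many distal→proximal mapping, short enough to keep attention over
raw frames cheap.

Per frame the 50 input features are five 10-dim sensor blocks in the fixed
order (left wrist, right wrist, left ankle, right ankle, torso):
L2-normalized quaternion, then z-normalized angular velocity and linear
acceleration. Normalization statistics are a single (μ, σ) pair per
sensor × modality pooled over all three axes — per-axis statistics would
distort the direction of inertial vectors — with σ floored at 1e−8 and the
standardized value clamped to ±5. The clamp retains erf(5/√2) ≈ 99.99994%
of a Gaussian, so genuinely fast motion survives while sensor transients
cannot blow up gradients. Statistics are frozen on the training partition
and reused at inference; recomputing them from a 120-frame buffer is
possible in principle but high-variance, so the frozen variant is the
default and the only one exercised here.

Targets reparameterize each joint's relative rotation
q_rel = q_proximal ⊗ q_distal⁻¹ by swing–twist about the anatomical limb
axis u = [1,0,0]: twist = normalize([w, (v·u)u]), swing = q_rel ⊗ twist⁻¹.
Supervising the swing alone removes the axial-twist channel that wrist
sensors measure worst. Target ω and a are expressed in the global frame and
z-normalized with proximal-joint training statistics (same ±5 clamp); the
prediction head therefore works in normalized units throughout and the
losses are computed in that space. Both choices (target frame, loss space)
are configuration points rather than laws; the defaults keep the regression
target distribution comparable across joints.

### Network

Encoder-only Transformer, pre-layer-norm: linear embedding 50→d_model with
bias, added sinusoidal positional encoding, then N blocks of (LN →
multi-head self-attention → dropout → residual; LN → GELU feed-forward →
dropout → residual), a final layer norm (standard for pre-norm stacks), and
four parallel per-joint linear heads of width 10 reading the last frame's
latent only. Predicted swing quaternions are L2-normalized before the loss
and in the output. Defaults d_model = 256, N = 6, 8 heads, d_ff = 1024,
dropout 0.1 give 4,762,408 trainable parameters; the commonly cited count
of ≈4.74 M for this architecture is not exactly attainable under any
embedding/head layout we enumerated, and we document the 0.4% discrepancy
rather than reverse-engineer one. `ModelConfig.reduced()` (d_model = 64,
2 layers, 4 heads, d_ff = 256; ≈106 k parameters) is the CPU-scale variant
used by the test suite and acceptance study.

The network, its backward pass, and AdamW (decoupled weight decay 0.01,
applied to matrices only) are written in NumPy. Gradients of every layer
are verified against central finite differences in the test suite; dropout
exists only in training mode, so evaluation is bit-deterministic.

### Loss

L_MTL = λ_q L_quat + λ_ω L_vel + λ_a L_acc, λ = (1.0, 0.1, 0.01).
L_quat = mean(1 − |q̂·q|) is smooth on S³ and invariant to the double cover
on either argument; the absolute value is used in both the training loss
and the reported per-frame form for consistency. L_vel and L_acc are
Smooth-L1 with knee 1 in normalized units; at |e| = 1 both branches agree
at 0.5 and the linear branch is taken. The velocity term is applied to
every batch by default — its reading as a hard-negative-only penalty is
available via `vel_loss_scope="hardneg"` — because the unconditional form
is the one the weighted sum expresses.

### Hard negatives

Distal-isolation sequences (locked-humerus elbow flexion at 0.5–2.0 Hz,
pronation/supination with the elbow fixed at 90°, seated knee extension)
are valid only if every proximal joint stays strictly below 0.1 rad/s at
every frame. Batches of 64 contain round-half-even(r·64) such windows
(floor 1 whenever r > 0), r = 0.1 by default, sampled without replacement
per epoch and reshuffled from the run seed; the hard-negative pool is
recycled when smaller than an epoch's demand.

## Post-processing

1. **Joint limits.** Each predicted relative rotation is mapped to an
   intrinsic Euler parameterization (per-joint order in the shipped
   `joint_limits.json`), each angle clipped, and the result re-projected to
   SO(3). The elbow/knee are hinges about the local z flexion axis with
   ranges [5°, 150°] / [0°, 140°]; the shoulder is a [−45°, 150°] box on
   all three Y-X-Z axes, and the hips mirror the shoulder box (no separate
   hip range is prescribed anywhere authoritative; the file is editable).
   Euler boxes are unambiguous only while the middle-axis angle stays in
   the canonical ±90° band — the calibration convention is assumed to place
   the anatomical workspace there. Clamping is idempotent and in-range
   rotations are fixed points (up to ~1e−5°, the arccos noise floor).
2. **MEKF.** Scalar-gain multiplicative Kalman filter per joint:
   K = (P+σ_p²)/(P+σ_p²+σ_m²), update q̂ ← exp(K·log(q_obs ⊗ q̂⁻¹)) ⊗ q̂,
   σ_p² = 10⁻⁶, σ_m² = 10⁻³. The covariance recursion
   P ← (1−K)(P+σ_p²) with P₀ = σ_m² is our choice (no authoritative rule
   exists for the scalar form); it decays to a stationary gain K ≈ 0.031,
   i.e. a ≈0.5 s low-pass at 60 Hz. Clamping runs before filtering so a
   late limit violation cannot re-introduce a jump into the smoothed
   trajectory.

Note that heavy smoothing trades jitter for lag: on the desk-scale models
the filter reliably cuts TSE but can *increase* MPJPE on fast motion, and
the swing-space shoulder box is conservative. Both stages can be toggled
independently for ablation.

## Evaluation

All metrics are root-relative to the sternum. Joint positions come from
rotating each proximal bone vector (humerus 30 cm, thigh 40 cm) by the
swing quaternion from fixed anchors (shoulder offset 20 cm, hip offset
10 cm on a canonical skeleton; both prediction and ground truth are
evaluated on the same skeleton, which is what retargeting reduces to here).
Because the bone vector lies along the twist axis, these positions are
exactly twist-invariant — the component the model does not predict cannot
move them. MPJPE averages Euclidean error over joint-frame pairs (cm);
PCK@σ uses a strict inequality; PCK-AUC is the exact integral of the PCK
curve over 0–15 cm divided by 15, computable in closed form as the mean
clipped-error survival 1 − E[min(e,15)]/15 (a perfect predictor scores
1.0). TSE converts positions to meters and compares discrete second
derivatives (Δt = 1/60 s), excluding boundary frames. All σ columns are
frame-wise: the per-frame mean over joints forms a series whose population
σ is reported, since joint errors within a frame are kinematically coupled
and an IID pooling would understate the spread.

## Synthetic data

The simulator is the package's data source and defines its study
conditions. A 9-segment skeleton (torso root, upper arms, forearms, upper
legs, shanks, with rigid shoulder/hip anchor offsets) is driven by
C∞ rotation-vector trajectories:

- **ADL-like motion:** per ball joint, up to three sinusoids per rotation
  axis with frequencies ≤ 2 Hz and total amplitude ≲ 0.65 rad about a
  random resting offset; hinge joints oscillate inside their anatomical
  range (rest 60–80°, excursion ≤ 55°). Two oscillators are shared across
  all joints so distal and proximal motion is genuinely coupled — this
  coupling is what a model without hard negatives learns to over-trust.
- **Isolation tasks:** the distal joint follows a pure sinusoid at the
  requested frequency (peak speed 2πfA); proximal joints carry only a
  5 mrad, 0.2 Hz wobble (peak ≈ 0.006 rad/s, 16× below the 0.1 rad/s
  validity bound).

Sensor orientation is the segment's composed global rotation times a
per-sensor mounting offset (removable exactly by boresight calibration
against the session's reference frame; offsets default to zero so the
feature path matches the calibrated-input convention). Angular velocity is
the central difference of the exact orientation mapped through the
quaternion log (second-order accurate; integrating it back reproduces the
trajectory within 0.5° over 2 s). Linear acceleration is the second
central difference of the sensor's global position, gravity-free by
default (`gravity_included` adds the −g reaction instead). Channel noise
is i.i.d. Gaussian on gyro/accelerometer channels only; for the noise
stress sweep, σ is interpreted in normalized-feature units and injected
after standardization, with the physical-unit variant available on the
stream.

What the simulator does **not** emulate: soft-tissue artifact, magnetometer
disturbance and heading drift, sensor bias instability, packet loss,
inter-subject anthropometric variation, and the long-tailed diversity of
real daily-living corpora. Passing tests therefore demonstrate that the
pipeline is internally correct and that its training signals act in the
documented directions at desk scale — not that real-corpus error magnitudes
are reproduced.

## Study sizes and determinism

The acceptance study trains the reduced model on 18 ADL + 6 isolation
sessions of 60 s each (~24 min of motion; stride-30 windowing gives ≈2100
training windows) for 8 epochs, twice (with r = 0.1 and r = 0), then
evaluates on held-out files at stride 4. These sizes were chosen once as a
single-core-friendly configuration that still shows monotone validation
convergence, a clear margin over the constant-T-pose baseline, the
hard-negative direction on isolation tasks, and the TSE reduction from
post-processing. Every random draw — trajectory synthesis, mounting
offsets, noise, partitioning, batch shuffling, weight init, dropout —
derives from one seed via independent seed sequences; two runs with the
same seed are bit-identical up to BLAS reduction order.

## Numerical choices

- Degenerate twist (‖[w, (v·u)u]‖ < 1e−12, a pure 180° swing orthogonal to
  the axis): twist = identity, swing = q_rel.
- Geodesic error uses 2·arccos(|w(Δq)|) so antipodal representations of the
  same rotation score 0°; sign canonicalization (w ≥ 0) happens only at
  serialization boundaries and in the log map, never inside loss gradients.
- quat log/exp switch to series expansions below 1e−8 to avoid 0/0.
- NaN repair in streams: gaps shorter than 3 frames are filled by
  shortest-arc normalized linear quaternion interpolation and linear
  inertial interpolation; anything longer, any ±Inf, or NaN at a stream
  boundary rejects the file ("extensive" is operationalized as ≥3 frames).
- Training stride 30 (4× overlap) balances data volume against window
  correlation; evaluation uses stride 1 (streaming-equivalent) or a small
  stride for pooled reports.
- Early stopping monitors validation L_MTL with patience 10 and restores
  the best-epoch weights.

## Known limitations

Desk-scale models are far from converged; their absolute errors are an
order of magnitude above what long training on a large natural-motion
corpus would give, and only directional/structural claims are tested. The
Euler-box clamp is meaningful only within the canonical middle-axis band.
The MEKF gain is fixed, not motion-adaptive. The simulator's ADL prior is
band-limited sinusoidal, far narrower than human motion. Streaming
inference recomputes the full window per frame (O(L²) attention per
prediction) — correct and equivalent to batch mode, but not optimized for
latency.
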