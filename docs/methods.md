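# Methods

`sdnet` implements a single-direction CNN-LSTM decoder for continuous joint
kinematics, together with the full synthetic harness needed to exercise it:
a two-link arm model, a center-out task simulator with direction-tuned Poisson
units, the spike/kinematic preprocessing chain, baseline and ablation decoders,
cross-target fine-tuning, and co-contraction estimation. This note records the
models, the default parameters and why they have those values, the numerical
choices, and what the synthetic experiments can and cannot show.

## Arm model

The limb is a planar two-link chain (shoulder at the origin, no gravity —
movements are in the horizontal plane). Angles: shoulder angle `θs` from the
+x axis; elbow angle `θe ∈ [−π, 0]` with `−π` full extension and `0` fully
folded, so the hand sits at

    x = l1 cosθs − l2 cos(θs+θe),   y = l1 sinθs − l2 sin(θs+θe)

and the inverse map is the standard two-arccos form (elbow on the canonical
branch). Defaults: `l1 = 0.132 m`, `l2 = 0.207 m`, `m1 = 0.295 kg`,
`m2 = 0.280 kg`, forearm CoG at `l2/2`. The segment inertias are not
independently specified; we default to uniform-rod values about the proximal
joint (`I = m l²/3`), overridable in `ArmParameters`.

Joint torques follow `T = M(θ) θ̈ + V(θ, θ̇)` with

    M11 = I1 + I2 + 2 m2 l1 lg2 cosθe + m2 l1²,
    M12 = M21 = I2 + m2 l1 lg2 cosθe,   M22 = I2,

and the Coriolis/centrifugal vector is the unique form consistent with that
inertia matrix,

    V = [−h (2 θ̇s θ̇e + θ̇e²),  h θ̇s²],   h = m2 l1 lg2 sinθe,

so torque-free simulations conserve energy (verified to 1e-4 relative). The
manipulandum (handle) is modelled as a planar point-mass pair acting at the
hand (`Mm = diag(0.565, 0.065) kg`), entering through the Jacobian as
`M → M + Jᵀ Mm J`; the handle's convective term is dropped (`Vm = 0`, the
masses are constant), a deliberate simplification — inverse dynamics and the
forward-simulation oracle use the same model, so round trips are exact
(torque recovery RMSE < 1e-6 N·m with RK4 at 0.1 ms steps).

## Task simulator

Each synthetic session emulates one recording day: 1–2 tuned units and a fixed
number of repetitions of planar center-out reaches to 8 targets, 0.08 m from a
home position at (0.17, −0.15) m in shoulder coordinates (inside the
comfortable workspace; the true workspace geometry of the original experiment
is not public, so these are declared configuration, not facts). Trials last
1800 ms sampled at 1 kHz with movement onset nominally at 300 ms. Reaches are
minimum-jerk (straight path, peak speed 1.875·d/T) over 600 ms with
per-repetition endpoint jitter (σ = 2 mm) and duration jitter (σ = 30 ms), plus
a configurable fraction (default 5%) of deviant trials whose heading is rotated
30–50° — these give the trial-selection stage genuine work.

Trajectory jitter is keyed by (master seed, target, repetition) and *shared
across sessions*, so pairing trials of equal repetition index across sessions —
the pseudo-population construction — yields kinematically consistent trials,
the synthetic analogue of "the subject repeated similar movements every day".
Spiking is keyed by (master seed, session, target, repetition, neuron), so any
subset of the dataset regenerates identically.

Each unit belongs to one of four directional modules (shoulder-extension,
shoulder-flexion, elbow-extension, elbow-flexion; "extension" denotes the
positive joint-coordinate direction) and encodes either the rectified
directional angular velocity or the directional torque of its joint:

    rate(t) = baseline + gain · drive(t + lag),

an inhomogeneous-Poisson rate with a neural *lead* of ~100 ms (σ = 20 ms) over
the movement, baselines 2–8 Hz, and gains (≈40 Hz/(rad/s), ≈150 Hz/(N·m),
log-normal spread 0.25) chosen to give 40–80 Hz peak modulation over the
default reach — ordinary motor-cortex-like numbers. Spikes are drawn by per-bin
thinning at 1 kHz.

Directional torques are defined as `τ_ext = max(τ, 0) + c(t)` and
`τ_flex = max(−τ, 0) + c(t)`, where `c(t) ≥ 0` is an optional commanded
co-contraction profile (Gaussian bump, σ = 150 ms, centred at movement end —
stabilisation at target hit). By construction `τ_ext − τ_flex = τ` exactly and
`min(τ_ext, τ_flex) = c(t)`: the simulator carries a ground truth that real
recordings cannot provide.

What the simulator does *not* emulate: electrode drift and unit instability
across days, non-Poisson spiking statistics, heterogeneous/mixed tuning,
postural signals, measurement noise on hand position. Passing the recovery
benchmarks therefore shows that the pipeline and decoder behave correctly on
data satisfying the model's own premises; it says nothing about decoding
accuracy on real cortical data.

## Preprocessing

All filters are zero-phase (forward–backward `filtfilt`), appropriate for an
offline pipeline. Firing rates: per-1-ms bin, the inverse inter-spike interval
of the spikes bracketing the bin (zero outside the recorded spike span), then a
4th-order Butterworth low-pass at 7 Hz, a 40-ms moving average, resampling on a
10-ms grid containing the movement onset exactly, and clipping at zero.
Kinematics: joint angles by inverse kinematics; angular velocities and
accelerations by central differences each low-passed at 5 Hz (4th order);
torques by inverse dynamics with the manipulandum coupling; downsampled to
100 Hz on the same onset-aligned grid. Movement onset is the first sample at
which the hand's tangential acceleration (the derivative of speed) reaches
0.8 m/s².

Trial selection (per target): the heading angle at 47 mm from home is clustered
by K-means (k = 3, 50 restarts, fixed seed; size ties broken by sorted centroid
order); the largest cluster is the reference, whose onset-aligned mean gives
x̄(t), ȳ(t) and mean speed v̄(t) over a 1500-sample window. A trial is kept iff
its trajectory error `s = (Σdx² + Σdy²)/T < 20 mm²` and its speed-profile
`R² > 0.6` against the reference. The error is implemented exactly as stated
(sum of squared deviations over both axes divided by T, units mm² — no square
root), with the threshold as printed.

Rates are z-scored per unit with statistics fitted on the training partition
only (constant units become zero channels); the alternative normalisation that
subtracts a cross-unit mean at each time point is available as
`mode="printed"` for comparison. Output variables are likewise z-scored per
output on the training partition; decoded series are mapped back to physical
units through the stored statistics.

The decoder input is the sliding-window tensor `[B × T × C × L]`: for each of
the `T = 180` output steps (10-ms grid spanning the 1800-ms trial, the first
step 300 ms before onset) the lag axis holds `L = 30` consecutive 10-ms samples
covering 200 ms before to 90 ms after the step (a 300-ms window). Windows
reaching past the recorded span are zero-padded after standardisation and
flagged. The window tensor is stored as a strided view of the padded rate
series, which also lets the convolutional stage run on the series directly
(below). The linear baseline uses the window-centre sample only,
`[(B·T) × C]`.

## Decoder

One decoder block maps the windowed tensor to a scalar series:

1. temporal convolution, 8 filters of kernel (1×30), same padding, over the
   lag axis;
2. depthwise spatial convolution over the unit axis, kernel (C×1), depth
   multiplier 2 (16 channels);
3. batch normalisation, then ReLU (the equations place one rectification after
   the composed convolutions);
4. average pooling (size/stride 4) along the lag axis — 30 → 7 positions,
   flattened to 7·16 = 112 features per step;
5. an LSTM with 16 hidden units over the 180 steps (standard sigmoid-gated
   recurrence with tanh cell/output; verified against a hand-rolled
   step-by-step reference);
6. a fully connected layer of 8 units with ReLU, dropout 0.5 (training only),
   a 1-unit readout head, batch normalisation, and the block's final
   activation.

The layer table ends at the 8-unit FC layer although each branch must emit a
scalar; the 1-unit readout head (9 parameters) is the minimal completion and
is reported explicitly by `count_parameters`. A single block at the study
geometry (73 units) has 9,833 core trainable parameters (conv 248 + depthwise
1,184 + LSTM 8,256 + FC 136 + head 9) ≈ 9.8 K, batch-norm parameters counted
separately; one extension/flexion branch pair is ≈ 19.7 K.

Architectures: `single_direction` uses one pair of blocks per output variable
(8 blocks for the 4 outputs: shoulder/elbow angular velocity and torque) with
rectified final activations, and reports `net = ext − flex`; `linear_head` is
the same without the rectifier (ablation); `shared` shares one CNN+LSTM trunk
across per-direction FC/readout heads (ablation); `conventional` is a single
block emitting all four outputs with linear activation (baseline). The closed
form linear baseline is ordinary least squares `β = (XᵀX)⁻¹XᵀP` (pseudo-inverse
under rank deficiency).

Implementation: no deep-learning framework is used — the network and a minimal
reverse-mode autodiff engine are built on numpy. Because batch normalisation
and the rectifier come after both convolutions, the two convolutions compose
linearly; the forward pass collapses the unit axis first and applies the
temporal kernel as a banded (Toeplitz) matrix on sliding windows of the 10-ms
series, avoiding the ~26× window redundancy while remaining exactly equal to
per-window 'same' convolution (`forward_windowed` provides the literal path,
and an equivalence test pins the two together). All eight branches evaluate as
one stacked batch. Gradients are checked against central differences for every
primitive and through the whole network.

## Training

MSE loss on the z-scored net outputs; Adam at 1e-3 (1e-4 for fine-tuning);
batch size 32; reduce-on-plateau scheduler (×0.1 after 15 epochs without
validation improvement); early stopping (patience 20) with best-validation
weight restoration; dropout 0.5. Splits operate on repetition groups — the
synchronised pseudo-trials that play the role of recording sessions in the
pseudo-population — and no group straddles a partition; 80/20 train+val/test,
with an inner 80/20 group split of the training set for validation (the source
protocol does not state the inner ratio). Normalisation statistics and trial
selection references are computed inside each split's training partition only;
five-fold cross-validation rotates group-level folds and trains fresh each
fold.

Cross-target fine-tuning freezes the convolutional feature extractor (both
kernels, biases, and the conv batch norm) and retrains the LSTM, FC, readout
and output-norm parameters at 1e-4 for at most 100 epochs on 20% of the unseen
target's trials (group-level), testing on the rest. During fine-tuning *all*
batch-norm layers normalise with their frozen pretrained running statistics
(inference mode): with ~10-trial fine-tune sets, batch statistics are so noisy
that letting them drive normalisation (or update the running averages)
systematically degraded the adapted decoder before it could improve — frozen-BN
transfer is the standard remedy and is used here.

## Co-contraction

Because both branch outputs are non-negative, simultaneous antagonist drive is
summarised as `τ_co = min(τ_ext, τ_flex)` with `τ_net = τ_ext − τ_flex`. On
simulator ground truth this identity recovers the commanded profile exactly.
For the *decoded* branches, however, the training signal constrains only the
difference: any common non-negative component added to both branches lies in
the null space of the loss, and dropout noise (which scales with activation
magnitude) actively favours the minimum-magnitude decomposition
`ext ≈ max(net, 0)`, `flex ≈ max(−net, 0)`. Empirically the trained branches
correlate > 0.95 with the rectified net output and the decoded co-contraction
carries essentially no trace of the commanded profile (Pearson r ≈ 0.0–0.1 on
the micro benchmark). The decoded co-contraction read-out should therefore be
treated as an unvalidated proxy: the estimator is implemented and tested
against ground truth, but net-only supervision does not identify the
decomposition. This limitation is intrinsic to the training signal, not to the
implementation.

## The micro benchmark

`sdnet.benchmark` commits one desk-scale recovery study used by the acceptance
suite and `scripts/acceptance.py`: 20 sessions × 2 units (40-unit
pseudo-population), 8 targets, 60 repetitions per target (~430 trials after
selection), 1800-ms trials (T = 180), injected co-contraction of 0.08 N·m.
Problem sizes and epoch caps — 18 epochs for the full fit, 30 for the
two-target pretrain, the protocol's full 100 for fine-tuning — are fixed
choices of the benchmark, sized so the whole study runs in minutes on one CPU
core; at these caps the full fit reaches held-out angular-velocity R² ≈ 0.8
(pooled, mean of shoulder and elbow) with the linear baseline clearly lower,
and fine-tuning on ~12 trials of a held-out target improves markedly over the
un-tuned two-target decoder.

## Numerical choices and degenerate inputs

* float32 throughout the network; float64 elsewhere.
* K-means ties, split assignment, dropout masks, weight init: all keyed to
  explicit seeds; identical seeds give bit-identical training histories.
* Batch-norm ε = 1e-5, momentum 0.1; LSTM forget-gate bias initialised to 1;
  Glorot-uniform weight init.
* Empty/single-spike trains give zero rate series (not an error); constant
  units become zero channels; unreachable hand samples raise with the first
  offending index; R² is undefined (error) for constant truth; zero-variance
  paired differences produce an explicit degenerate report instead of NaN.
* Average pooling uses floor semantics (30 → 7, the last 2 lags unused).
* The elbow convention range is enforced on reconstruction by clipping with a
  flag, never silently.
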