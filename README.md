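# sdnet — single-direction CNN-LSTM decoding of joint kinematics from spikes

`sdnet` is a brain–machine-interface decoding toolbox for continuous joint
kinematics. Its core model is the **Single-Direction CNN-LSTM** ("SingleNet"):
instead of one monolithic network predicting all movement variables, each joint
variable v (shoulder/elbow angular velocity and torque) is estimated by a
*pair* of rectified CNN-LSTM branches — one for extension, one for flexion —

    He,v(t) ≥ 0,   Hf,v(t) ≥ 0,   v̂(t) = He,v(t) − Hf,v(t),

reflecting the observation that opposite rotation directions of a joint are
encoded by distinct motor-cortical populations. Each branch is an
EEGNet-style block: temporal convolution (8 filters, 1×30, same padding) →
depthwise spatial convolution over units (C×1, depth multiplier 2) → batch
norm → ReLU → average pooling (4) → 112 features/step → LSTM (16 hidden) →
FC(8) → scalar readout → batch norm → ReLU. Because both branch outputs are
non-negative, antagonist co-activation can be summarised as
`τ_co = min(τ_ext, τ_flex)`.

The original recordings (a macaque center-out reaching task) are not public,
so the package ships a first-class synthetic harness that reproduces the
study design end to end: a two-link planar arm (inverse kinematics/dynamics
with manipulandum coupling), a pseudo-population simulator (1–2 direction-
tuned Poisson units per session, repetition-matched across sessions), the
preprocessing chain (inverse-ISI rates, 7 Hz/5 Hz zero-phase filtering, onset
detection at 0.8 m/s², K-means trial selection, per-unit z-scoring, 300-ms
sliding windows), conventional CNN-LSTM / shared-trunk / linear-activation
ablations, an OLS baseline, group-level cross-validation with paired t-tests
and Benjamini–Hochberg FDR, and cross-target fine-tuning (frozen convolutional
extractor, 20% of an unseen target's trials).

No deep-learning framework is required: the network, a minimal reverse-mode
autodiff engine, Adam, and the training loop are implemented on numpy and run
comfortably on a single CPU core. See `docs/methods.md` for the models,
defaults and numerical choices.

## Worked example

```python
from sdnet import DecoderModel, TaskConfig, TrainingConfig

model = DecoderModel.from_simulation(
    TaskConfig(n_sessions=6, trials_per_target=20, cocontraction_amplitude=0.05),
    seed=7,
    architecture="single_direction",
    training=TrainingConfig(max_epochs=10, early_stop_patience=5),
)
res = model.fit(seed=0)
print(res.summary())
```

prints

```
Single-Direction CNN-LSTM decoder fit
======================================================
architecture:     single_direction
units (C):        12
time steps (T):   180
trials train/test:113/30
epochs run:       10
final val loss:   0.6117
------------------------------------------------------
held-out R^2 (pooled):
  shoulder_av           0.839
  elbow_av              0.342
  shoulder_torque       0.268
  elbow_torque          0.158
======================================================
```

i.e. with only 12 synthetic units and ten epochs the decoder already explains
~84% of held-out shoulder angular-velocity variance; the elbow and the torques
(smaller, noisier drives) trail behind at this tiny scale, and all four scores
rise with more units, trials and epochs (the 40-unit micro benchmark reaches
≈0.95/0.68 angular-velocity R², see `scripts/acceptance.py`). From `res` you can go further: `res.predict()` returns the decoded
series in physical units together with the non-negative branch series,
`res.cocontraction(joint=0)` applies the min-rule to the shoulder torque pair,
`res.finetune(target=2)` runs the cross-target adaptation protocol, and
`res.plot_trajectories()` overlays hand paths reconstructed from the decoded
angular velocities on the ground truth.

A `sdnet` command-line interface binds the same pipeline to artifacts on disk
(`sdnet simulate | preprocess | train | finetune | evaluate | ablate | report
--config run.yaml --out DIR`), with every artifact stamped with the config
hash and seed.

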