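"""Model/Results front end for fitting decoders to a dataset.

Follows the fit-from-data idiom: a :class:`DecoderModel` is built from a
:class:`~sdnet.datasets.DecodingDataset` (or simulated on the fly), ``fit()``
trains the network and returns a :class:`DecoderResults` carrying the fitted
decoder, held-out scores, training history and a ``summary()`` table;
simulation-based prediction, co-contraction estimation, weight introspection
and plotting hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arm import ArmParameters, ManipulandumParameters
from .datasets import DecodingDataset, build_dataset
from .decoders import estimate_cocontraction, extract_feature_weights
from .evaluation import r_squared, reconstruct_trajectory
from .network import DecoderBlockConfig
from .simulate import TaskConfig, generate_sessions
from .training import (SplitPlan, TrainedDecoder, TrainingConfig, cross_validate,
                       evaluate_r2, finetune_decoder, train_decoder)

__all__ = ["DecoderModel", "DecoderResults"]


class DecoderModel:
    """A decoder architecture bound to a dataset, ready to fit.

    Parameters
    ----------
    dataset : DecodingDataset
        Trial-matched population rates and kinematic labels.
    architecture : str
        ``single_direction`` (default), ``conventional``, ``shared`` or
        ``linear_head``.
    training : TrainingConfig
        Optimisation hyperparameters.
    targets : sequence of int, optional
        Restrict training to these reach targets (for cross-target
        pretraining); by default all targets are used.
    """

    def __init__(self, dataset: DecodingDataset, architecture: str = "single_direction",
                 training: TrainingConfig = TrainingConfig(),
                 block: Optional[DecoderBlockConfig] = None,
                 targets: Optional[Sequence[int]] = None):
        self.dataset = dataset
        self.architecture = architecture
        self.training = training
        self.block = block
        self.targets = None if targets is None else np.asarray(targets)

    @classmethod
    def from_simulation(cls, task: TaskConfig = TaskConfig(),
                        arm: ArmParameters = ArmParameters(),
                        manip: Optional[ManipulandumParameters] = None,
                        seed: int = 0, **kwargs) -> "DecoderModel":
        """Simulate sessions, assemble the dataset, and bind a model to it."""
        sessions = generate_sessions(task, arm, manip, master_seed=seed)
        return cls(build_dataset(sessions, task, arm, manip), **kwargs)

    def _pool(self) -> np.ndarray:
        if self.targets is None:
            return np.arange(self.dataset.n_trials)
        return np.flatnonzero(np.isin(self.dataset.targets, self.targets))

    def fit(self, seed: int = 0, test_fraction: Optional[float] = None) -> "DecoderResults":
        """Train on a group-level split and score the held-out trials."""
        pool = self._pool()
        frac = self.training.test_fraction if test_fraction is None else test_fraction
        plan = SplitPlan.from_groups(self.dataset.groups[pool], frac, seed=seed)
        tr_local, te_local = plan.indices(self.dataset.groups[pool])
        train_idx, test_idx = pool[tr_local], pool[te_local]
        decoder = train_decoder(self.dataset, train_idx, self.architecture,
                                self.training, seed=seed, block=self.block)
        scores = (evaluate_r2(decoder, self.dataset, test_idx)
                  if len(test_idx) else {})
        return DecoderResults(self, decoder, train_idx, test_idx, scores, seed)

    def fit_cv(self, seed: int = 0) -> pd.DataFrame:
        """K-fold cross-validation (fresh decoder per fold); tidy score table."""
        ds = (self.dataset if self.targets is None
              else self.dataset.subset(self._pool()))
        return cross_validate(ds, self.architecture, self.training, seed=seed,
                              block=self.block)


@dataclass
class DecoderResults:
    """A fitted decoder with its held-out scores and diagnostics."""

    model: DecoderModel
    decoder: TrainedDecoder
    train_idx: np.ndarray
    test_idx: np.ndarray
    r2: dict
    seed: int
    _pred_cache: dict = field(default_factory=dict, repr=False)

    @property
    def history(self) -> pd.DataFrame:
        return self.decoder.history

    def predict(self, index: Optional[np.ndarray] = None) -> dict:
        """Decoded outputs (physical units) for the given trials (default: test)."""
        index = self.test_idx if index is None else np.asarray(index)
        key = hash(index.tobytes())
        if key not in self._pred_cache:
            self._pred_cache[key] = self.decoder.predict(self.model.dataset, index)
        return self._pred_cache[key]

    def finetune(self, target: int, seed: int = 0):
        """Cross-target adaptation; see :func:`sdnet.training.finetune_decoder`."""
        return finetune_decoder(self.decoder, self.model.dataset, target,
                                self.model.training, seed=seed)

    def cocontraction(self, index: Optional[np.ndarray] = None,
                      joint: int = 0) -> dict:
        """Decoded net and co-contraction torque series for one joint.

        ``joint`` 0 = shoulder, 1 = elbow.  Uses the torque branch pair;
        requires a branched architecture.  Returns physical-unit series plus
        the dataset's commanded co-contraction for comparison.
        """
        index = self.test_idx if index is None else np.asarray(index)
        pred = self.predict(index)
        if "ext" not in pred:
            raise ValueError("co-contraction needs a branched (single-direction) decoder")
        v = 2 + joint   # torque outputs follow the two angular velocities
        net, co = estimate_cocontraction(pred["ext"][..., v], pred["flex"][..., v])
        out = {"net": net, "cocontraction": co,
               "truth_net": self.model.dataset.labels[index][..., v]}
        if "coco" in self.model.dataset.aux:
            out["commanded"] = self.model.dataset.aux["coco"][index]
        return out

    def feature_weights(self, mode: str = "spatial") -> pd.DataFrame:
        return extract_feature_weights(self.decoder.network, mode)

    def reconstruct(self, trial: int) -> dict:
        """Hand path reconstructed from decoded angular velocities for a trial."""
        ds = self.model.dataset
        local = np.flatnonzero(self.test_idx == trial)
        pred = self.predict()["net"] if local.size else self.predict(np.array([trial]))["net"]
        row = pred[local[0]] if local.size else pred[0]
        theta0 = ds.aux["theta"][trial][0]
        path, clipped = reconstruct_trajectory(row[:, :2], theta0)
        return {"path": path, "clipped": clipped, "truth": ds.aux["hand"][trial]}

    def summary(self) -> str:
        """Human-readable fit summary."""
        ds = self.model.dataset
        lines = [
            "Single-Direction CNN-LSTM decoder fit"
            if self.model.architecture == "single_direction"
            else f"CNN-LSTM decoder fit ({self.model.architecture})",
            "=" * 54,
            f"architecture:     {self.model.architecture}",
            f"units (C):        {ds.n_units}",
            f"time steps (T):   {ds.n_steps}",
            f"trials train/test:{len(self.train_idx)}/{len(self.test_idx)}",
            f"epochs run:       {len(self.history)}",
            f"final val loss:   {self.history['val_loss'].iloc[-1]:.4f}"
            if len(self.history) else "final val loss:   n/a",
            "-" * 54,
            "held-out R^2 (pooled):",
        ]
        for name, val in self.r2.items():
            lines.append(f"  {name:<18s} {val:8.3f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    # ------------------------------------------------------------- plotting
    def plot_trajectories(self, ax=None, max_trials: int = 40):
        """Overlay reconstructed test-trial hand paths on the ground truth."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ds = self.model.dataset
        for trial in self.test_idx[:max_trials]:
            rec = self.reconstruct(int(trial))
            ax.plot(rec["truth"][:, 0], rec["truth"][:, 1], color="0.7", lw=0.6)
            ax.plot(rec["path"][:, 0], rec["path"][:, 1],
                    color=f"C{ds.targets[trial] % 10}", lw=0.8)
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        ax.set_aspect("equal")
        ax.set_title("decoded (colour) vs true (grey) hand paths")
        return ax

    def plot_r2(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        names = list(self.r2)
        ax.bar(range(len(names)), [self.r2[n] for n in names])
        ax.set_xticks(range(len(names)), names, rotation=30, ha="right")
        ax.set_ylabel("held-out $R^2$")
        ax.set_ylim(None, 1.0)
        return ax
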