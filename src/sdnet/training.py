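"""Decoder training: optimisation loop, splits, cross-validation, fine-tuning.

Training minimises mean squared error on z-scored outputs with Adam
(learning rate 1e-3; 1e-4 for fine-tuning), a reduce-on-plateau scheduler
(factor 0.1, patience 15 epochs on the validation loss), early stopping
(patience 20) with best-validation weight restoration, and batch size 32.

Splits operate on *repetition groups* — the synchronised pseudo-trials that
play the role of recording sessions in the pseudo-population design — so no
group ever straddles partitions.  Normalisation statistics are always fitted
inside the training partition of the split at hand (leakage guard).

Fine-tuning freezes the convolutional feature extractor (both conv layers and
their batch norm) and adapts only the LSTM, FC and readout layers on a small
fraction (default 20%) of an unseen target's trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .datasets import DecodingDataset
from .evaluation import r_squared
from .network import DecoderBlockConfig, DecoderNetwork, mse_loss
from .preprocess import zscore_units

__all__ = ["TrainingConfig", "SplitPlan", "Adam", "TrainedDecoder",
           "train_decoder", "finetune_decoder", "cross_validate", "evaluate_r2"]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters (defaults follow the study protocol)."""

    learning_rate: float = 1e-3
    finetune_learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 1000
    finetune_max_epochs: int = 100
    scheduler_factor: float = 0.1
    scheduler_patience: int = 15
    early_stop_patience: int = 20
    val_fraction: float = 0.2
    test_fraction: float = 0.2
    finetune_fraction: float = 0.2
    folds: int = 5
    zscore_mode: str = "per_unit"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early-stopping patience must be below max epochs")


@dataclass
class SplitPlan:
    """Group-level train/validation/test assignment.

    Groups are repetition indices (synchronised pseudo-trials); a group is
    never split across partitions.
    """

    train_groups: np.ndarray
    test_groups: np.ndarray

    @staticmethod
    def counts(trials_per_target: int, n_targets: int,
               test_fraction: float = 0.2) -> dict:
        """Split accounting: trial counts under a group-level 80/20 split."""
        test_reps = int(round(test_fraction * trials_per_target))
        train_reps = trials_per_target - test_reps
        return {"train_val": train_reps * n_targets, "test": test_reps * n_targets,
                "train_reps_per_target": train_reps, "test_reps_per_target": test_reps}

    @classmethod
    def from_groups(cls, groups: np.ndarray, test_fraction: float = 0.2,
                    seed: int = 0) -> "SplitPlan":
        uniq = np.unique(groups)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(uniq)
        n_test = int(round(test_fraction * len(uniq)))
        return cls(np.sort(perm[n_test:]), np.sort(perm[:n_test]))

    def indices(self, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        groups = np.asarray(groups)
        return (np.flatnonzero(np.isin(groups, self.train_groups)),
                np.flatnonzero(np.isin(groups, self.test_groups)))


def group_kfold(groups: np.ndarray, k: int, seed: int = 0) -> list:
    """Disjoint, exhaustive group-level folds as (train_idx, test_idx) pairs."""
    uniq = np.unique(groups)
    if len(uniq) < k:
        raise ValueError(f"{len(uniq)} groups cannot form {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    folds = []
    for part in np.array_split(perm, k):
        test = np.flatnonzero(np.isin(groups, part))
        train = np.flatnonzero(~np.isin(groups, part))
        folds.append((train, test))
    return folds


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: Sequence, lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


@dataclass
class TrainedDecoder:
    """A fitted decoder: network weights plus attached normalisation state."""

    network: DecoderNetwork
    rate_stats: dict
    label_stats: dict
    training_config: TrainingConfig
    history: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def standardize(self, dataset: DecodingDataset) -> np.ndarray:
        z, _ = zscore_units(dataset.rates, stats=self.rate_stats)
        return z.astype(np.float32)

    def predict(self, dataset: DecodingDataset, index: Optional[np.ndarray] = None,
                batch_size: int = 64) -> dict:
        """Decode a dataset (evaluation mode): returns physical-unit net outputs
        and, for branched architectures, the non-negative branch series."""
        ds = dataset if index is None else dataset.subset(np.asarray(index))
        series = self.standardize(ds)
        nets, exts, flexs = [], [], []
        for lo in range(0, series.shape[0], batch_size):
            out = self.network.forward_series(series[lo:lo + batch_size], training=False)
            nets.append(out["net"].data)
            if out["ext"] is not None:
                exts.append(out["ext"].data)
                flexs.append(out["flex"].data)
        net_z = np.concatenate(nets)
        mean, sd = self.label_stats["mean"], self.label_stats["sd"]
        result = {"net_z": net_z, "net": net_z * sd + mean}
        if exts:
            ext_z = np.concatenate(exts)
            flex_z = np.concatenate(flexs)
            # branch series scaled back to physical units (shared offset stays
            # on the net output: net = ext_scaled - flex_scaled + mean)
            result.update({"ext_z": ext_z, "flex_z": flex_z,
                           "ext": ext_z * sd, "flex": flex_z * sd})
        return result

    def clone_network(self, inference_bn: bool = False) -> DecoderNetwork:
        net = DecoderNetwork.from_config(self.network.config_dict())
        net.load_state_dict(self.network.state_dict())
        net.inference_bn = inference_bn
        return net


def _batched_eval_loss(network: DecoderNetwork, series: np.ndarray,
                       labels: np.ndarray, batch_size: int) -> float:
    total, n = 0.0, 0
    for lo in range(0, series.shape[0], batch_size):
        out = network.forward_series(series[lo:lo + batch_size], training=False)
        b = out["net"].data.shape[0]
        total += float(np.mean((out["net"].data - labels[lo:lo + batch_size]) ** 2)) * b
        n += b
    return total / max(n, 1)


def _fit_loop(network: DecoderNetwork, train_series, train_y, val_series, val_y,
              cfg: TrainingConfig, seed: int, finetune: bool) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    names = network.trainable_names(finetune)
    opt = Adam([network.params[n] for n in names],
               lr=cfg.finetune_learning_rate if finetune else cfg.learning_rate)
    max_epochs = cfg.finetune_max_epochs if finetune else cfg.max_epochs
    best_val, best_state = math.inf, network.state_dict()
    stall_sched = stall_stop = 0
    records = []
    B = train_series.shape[0]
    for epoch in range(max_epochs):
        perm = rng.permutation(B)
        train_loss, seen = 0.0, 0
        for lo in range(0, B, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            out = network.forward_series(train_series[idx], training=True, rng=rng)
            loss = mse_loss(out["net"], train_y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} (lr={opt.lr:g}); "
                    "check input scaling")
            ad.backward(loss)
            opt.step()
            opt.zero_grad()
            train_loss += float(loss.data) * len(idx)
            seen += len(idx)
        val_loss = _batched_eval_loss(network, val_series, val_y, cfg.batch_size)
        records.append({"epoch": epoch, "train_loss": train_loss / seen,
                        "val_loss": val_loss, "lr": opt.lr})
        if val_loss < best_val - 1e-12:
            best_val, best_state = val_loss, network.state_dict()
            stall_sched = stall_stop = 0
        else:
            stall_sched += 1
            stall_stop += 1
        if stall_stop >= cfg.early_stop_patience:
            break
        if stall_sched >= cfg.scheduler_patience:
            opt.lr *= cfg.scheduler_factor
            stall_sched = 0
    network.load_state_dict(best_state)
    return pd.DataFrame(records)


def _val_split(groups: np.ndarray, train_idx: np.ndarray, fraction: float,
               seed: int) -> tuple[np.ndarray, np.ndarray]:
    sub = SplitPlan.from_groups(groups[train_idx], test_fraction=fraction, seed=seed)
    tr, va = sub.indices(groups[train_idx])
    if len(va) == 0 or len(tr) == 0:     # single group: fall back to trial split
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(train_idx))
        n_val = max(1, int(round(fraction * len(train_idx))))
        va, tr = perm[:n_val], perm[n_val:]
    return train_idx[tr], train_idx[va]


def train_decoder(dataset: DecodingDataset, train_idx: np.ndarray,
                  architecture: str = "single_direction",
                  config: TrainingConfig = TrainingConfig(), seed: int = 0,
                  block: Optional[DecoderBlockConfig] = None,
                  val_idx: Optional[np.ndarray] = None) -> TrainedDecoder:
    """Train a decoder on the given trials.

    Rate and label z-scoring statistics are fitted on the training partition
    only; an inner group-level validation split (default 20% of training
    groups) drives the scheduler and early stopping.
    """
    train_idx = np.asarray(train_idx)
    if val_idx is None:
        train_idx, val_idx = _val_split(dataset.groups, train_idx,
                                        config.val_fraction, seed)
    z, rate_stats = zscore_units(dataset.rates, train_index=train_idx,
                                 mode=config.zscore_mode)
    y_mean = dataset.labels[train_idx].mean(axis=(0, 1))
    y_sd = dataset.labels[train_idx].std(axis=(0, 1))
    y_sd = np.where(y_sd > 0, y_sd, 1.0)
    label_stats = {"mean": y_mean, "sd": y_sd}
    yz = ((dataset.labels - y_mean) / y_sd).astype(np.float32)
    series = z.astype(np.float32)

    network = DecoderNetwork(architecture, dataset.n_units, dataset.outputs,
                             block=block, seed=seed)
    history = _fit_loop(network, series[train_idx], yz[train_idx],
                        series[val_idx], yz[val_idx], config, seed, finetune=False)
    meta = {"seed": seed, "train_idx": train_idx, "val_idx": val_idx,
            "dataset_fingerprint": dataset.fingerprint(),
            "stats_fingerprint": float(np.sum(rate_stats["mean"]) + np.sum(y_mean))}
    return TrainedDecoder(network, rate_stats, label_stats, config, history, meta)


def finetune_decoder(pretrained: TrainedDecoder, dataset: DecodingDataset,
                     target: int, config: Optional[TrainingConfig] = None,
                     seed: int = 0) -> tuple[TrainedDecoder, np.ndarray, np.ndarray]:
    """Adapt a pretrained decoder to an unseen target.

    Uses ``finetune_fraction`` (default 20%) of the target's trials for
    fine-tuning and reserves the rest for testing; convolutional layers are
    frozen bit-exactly.  Returns (fine-tuned decoder, finetune_idx, test_idx).
    """
    config = config or pretrained.training_config
    target_idx = np.flatnonzero(dataset.targets == target)
    if len(target_idx) == 0:
        raise ValueError(f"dataset has no trials for target {target}")
    plan = SplitPlan.from_groups(dataset.groups[target_idx],
                                 test_fraction=1.0 - config.finetune_fraction,
                                 seed=seed)
    ft_local, test_local = plan.indices(dataset.groups[target_idx])
    ft_idx, test_idx = target_idx[ft_local], target_idx[test_local]
    if len(ft_idx) == 0:
        raise ValueError("fine-tuning set is empty")

    network = pretrained.clone_network(inference_bn=True)
    series = pretrained.standardize(dataset)
    mean, sd = pretrained.label_stats["mean"], pretrained.label_stats["sd"]
    yz = ((dataset.labels - mean) / sd).astype(np.float32)
    ft_train, ft_val = _val_split(dataset.groups, ft_idx, config.val_fraction, seed)
    history = _fit_loop(network, series[ft_train], yz[ft_train],
                        series[ft_val], yz[ft_val], config, seed, finetune=True)
    tuned = TrainedDecoder(network, pretrained.rate_stats, pretrained.label_stats,
                           config, history,
                           {**pretrained.meta, "finetuned_target": target,
                            "finetune_idx": ft_idx, "seed": seed})
    return tuned, ft_idx, test_idx


def evaluate_r2(decoder: TrainedDecoder, dataset: DecodingDataset,
                index: np.ndarray) -> dict:
    """Pooled per-output coefficient of determination on the given trials."""
    pred = decoder.predict(dataset, index)["net"]
    truth = dataset.labels[np.asarray(index)]
    return {name: r_squared(truth[..., v].ravel(), pred[..., v].ravel())
            for v, name in enumerate(dataset.outputs)}


def cross_validate(dataset: DecodingDataset, architecture: str = "single_direction",
                   config: TrainingConfig = TrainingConfig(), seed: int = 0,
                   block: Optional[DecoderBlockConfig] = None) -> pd.DataFrame:
    """Group-level k-fold cross-validation; each fold trains fresh.

    Normalisation and the inner validation split are recomputed inside each
    fold from its training partition only.  Returns a tidy table of per-fold,
    per-output R^2.
    """
    folds = group_kfold(dataset.groups, config.folds, seed)
    rows = []
    for f, (train, test) in enumerate(folds):
        dec = train_decoder(dataset, train, architecture, config,
                            seed=seed + f, block=block)
        scores = evaluate_r2(dec, dataset, test)
        for name, r2 in scores.items():
            rows.append({"fold": f, "output": name, "r2": r2,
                         "n_train": len(train), "n_test": len(test)})
    return pd.DataFrame(rows)
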