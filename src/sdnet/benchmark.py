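"""The committed micro benchmark: a fixed, desk-scale recovery study.

Defines one synthetic study — 20 sessions x 2 units (40-unit pseudo-population),
8 targets, 60 repetitions per target, 1800-ms trials, injected co-contraction —
together with the training protocol used to assess it:

* full fit on all targets with a repetition-group 80/20 split;
* pretraining on the two-target pair (Targets IV & V, 0-based 3 & 4) followed by
  output-layer fine-tuning on 20% of an unseen target's trials;
* co-contraction recovery scored as the Pearson correlation between the decoded
  ``min(extension, flexion)`` torque branches and the commanded profile.

Problem sizes and epoch caps are fixed, documented choices of this benchmark
(see docs/methods.md); they are deliberately small enough to run on a single
CPU in minutes.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .datasets import DecodingDataset, build_dataset
from .decoders import estimate_cocontraction
from .simulate import TaskConfig, generate_sessions
from .training import (SplitPlan, TrainedDecoder, TrainingConfig, evaluate_r2,
                       finetune_decoder, train_decoder)

__all__ = ["MICRO_TASK", "MICRO_TRAINING", "build_micro_dataset", "fit_full",
           "pretrain_pair", "finetune_gain", "cocontraction_recovery",
           "PRETRAIN_TARGETS"]

MICRO_TASK = TaskConfig(
    n_sessions=20, trials_per_target=60, neurons_per_session=2,
    cocontraction_amplitude=0.08)

# epoch caps sized for the micro benchmark; early stopping may end sooner.
# fine-tuning keeps the full 100-epoch budget of the study protocol.
MICRO_TRAINING = TrainingConfig(max_epochs=18, early_stop_patience=10)
PRETRAIN_TRAINING = TrainingConfig(max_epochs=30, early_stop_patience=20,
                                   finetune_max_epochs=100)
PRETRAIN_TARGETS = (3, 4)      # Targets IV & V


def build_micro_dataset(seed: int = 0) -> DecodingDataset:
    sessions = generate_sessions(MICRO_TASK, master_seed=seed)
    return build_dataset(sessions, MICRO_TASK)


def fit_full(dataset: DecodingDataset, seed: int = 0,
             architecture: str = "single_direction"):
    """Train on all targets (80/20 repetition-group split); return scores too."""
    plan = SplitPlan.from_groups(dataset.groups, MICRO_TRAINING.test_fraction,
                                 seed=seed)
    train_idx, test_idx = plan.indices(dataset.groups)
    decoder = train_decoder(dataset, train_idx, architecture, MICRO_TRAINING,
                            seed=seed)
    r2 = evaluate_r2(decoder, dataset, test_idx)
    return decoder, train_idx, test_idx, r2


def pretrain_pair(dataset: DecodingDataset, seed: int = 0,
                  targets: Sequence[int] = PRETRAIN_TARGETS) -> TrainedDecoder:
    """Pretrain on the two-target pair only (all their trials)."""
    idx = np.flatnonzero(np.isin(dataset.targets, np.asarray(targets)))
    return train_decoder(dataset, idx, "single_direction", PRETRAIN_TRAINING,
                         seed=seed)


def finetune_gain(dataset: DecodingDataset, pretrained: TrainedDecoder,
                  target: int, seed: int) -> dict:
    """Fine-tune on 20% of an unseen target's trials; compare with the
    un-tuned pretrained decoder on the same held-out trials.

    The comparison metric is the mean R^2 over the four output variables.
    """
    tuned, ft_idx, test_idx = finetune_decoder(pretrained, dataset, target,
                                               PRETRAIN_TRAINING, seed=seed)
    before = evaluate_r2(pretrained, dataset, test_idx)
    after = evaluate_r2(tuned, dataset, test_idx)
    return {"target": target, "seed": seed,
            "r2_pretrained": float(np.mean(list(before.values()))),
            "r2_finetuned": float(np.mean(list(after.values()))),
            "improved": float(np.mean(list(after.values())))
                        > float(np.mean(list(before.values()))),
            "per_output_before": before, "per_output_after": after,
            "n_finetune": len(ft_idx), "n_test": len(test_idx)}


def cocontraction_recovery(dataset: DecodingDataset, decoder: TrainedDecoder,
                           test_idx: np.ndarray) -> dict:
    """Correlate decoded co-contraction with the commanded profile.

    Uses both torque branch pairs (shoulder and elbow), pooled over the test
    trials; the commanded profile is identical for the two joints by
    construction, so both joints are scored against it and pooled.
    """
    pred = decoder.predict(dataset, test_idx)
    commanded = dataset.aux["coco"][np.asarray(test_idx)]
    est, cmd = [], []
    for joint in (0, 1):
        v = 2 + joint
        _, co = estimate_cocontraction(pred["ext"][..., v], pred["flex"][..., v])
        est.append(co.ravel())
        cmd.append(commanded.ravel())
    est, cmd = np.concatenate(est), np.concatenate(cmd)
    r = float(np.corrcoef(est, cmd)[0, 1])
    return {"pearson_r": r, "n_samples": est.size}
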