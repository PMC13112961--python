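"""Assembly of decoder-ready datasets from simulated sessions.

Chains the pseudo-population pairing, onset detection, trial selection,
rate/kinematic preprocessing, and carries the ground-truth directional torques
and commanded co-contraction alongside, so that decoders can be scored against
quantities the preprocessing itself never sees.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arm import ArmParameters, ManipulandumParameters
from .preprocess import (RESAMPLE_MS, compute_firing_rates, detect_onset,
                         process_kinematics, select_trials)
from .simulate import PopulationDataset, Session, TaskConfig, build_pseudopopulation

__all__ = ["DecodingDataset", "build_dataset", "OUTPUT_NAMES"]

OUTPUT_NAMES = ("shoulder_av", "elbow_av", "shoulder_torque", "elbow_torque")


@dataclass
class DecodingDataset:
    """Trial-matched population rates and kinematic labels on the 10-ms grid."""

    rates: np.ndarray               # [B, S, U] Hz, unstandardized
    rate_offsets_ms: np.ndarray     # [S] relative to onset
    labels: np.ndarray              # [B, T, V] physical units
    output_offsets_ms: np.ndarray   # [T]
    targets: np.ndarray             # [B]
    groups: np.ndarray              # [B] repetition / pseudo-session index
    outputs: tuple = OUTPUT_NAMES
    aux: dict = field(default_factory=dict)      # theta, hand, tau_ext, tau_flex, coco
    provenance: list = field(default_factory=list)
    selection: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_units(self) -> int:
        return self.rates.shape[2]

    @property
    def n_steps(self) -> int:
        return self.labels.shape[1]

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.meta, sort_keys=True, default=str).encode())
        for arr in (self.rates, self.labels, self.targets, self.groups):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]

    def subset(self, index: np.ndarray) -> "DecodingDataset":
        index = np.asarray(index)
        return DecodingDataset(
            self.rates[index], self.rate_offsets_ms, self.labels[index],
            self.output_offsets_ms, self.targets[index], self.groups[index],
            self.outputs, {k: v[index] for k, v in self.aux.items()},
            self.provenance, self.selection, dict(self.meta))

    def trial_table(self) -> pd.DataFrame:
        return pd.DataFrame({"target": self.targets, "group": self.groups})


def _grid_lookup(values: np.ndarray, offsets: np.ndarray,
                 wanted: np.ndarray) -> np.ndarray:
    """Sample ``values`` (first axis on ``offsets``) at ``wanted`` offsets, edge-held."""
    pos = np.round((wanted - offsets[0]) / RESAMPLE_MS).astype(int)
    pos = np.clip(pos, 0, len(offsets) - 1)
    return values[pos]


def build_dataset(sessions: Sequence[Session], config: TaskConfig,
                  arm: ArmParameters = ArmParameters(),
                  manip: Optional[ManipulandumParameters] = None,
                  apply_selection: bool = True,
                  selection_seed: int = 0) -> DecodingDataset:
    """Build the decoder-ready dataset from simulated sessions.

    Output steps span the full trial (``trial_ms / 10`` steps, the first one
    300 ms before onset); the rate series keeps every 10-ms sample the trial
    covers so windowing needs minimal zero padding.
    """
    if manip is None:
        manip = ManipulandumParameters()
    population: PopulationDataset = build_pseudopopulation(sessions)
    trials = population.trials

    onsets = [detect_onset(t.reference.path, config.fs) for t in trials]

    keep = np.ones(len(trials), dtype=bool)
    selection_reports = {}
    if apply_selection:
        for target in sorted({t.target for t in trials}):
            idx = [i for i, t in enumerate(trials) if t.target == target]
            rep = select_trials([trials[i].reference.path for i in idx],
                                [onsets[i] for i in idx],
                                home=np.asarray(config.home), fs=config.fs,
                                seed=selection_seed)
            selection_reports[target] = rep
            for local, i in enumerate(idx):
                keep[i] = bool(rep.table.loc[local, "keep"])

    T = config.trial_ms // RESAMPLE_MS
    out_offsets = np.arange(T) * RESAMPLE_MS - config.pre_onset_ms
    # common onset-aligned rate grid spanning exactly the window coverage
    # [first step - 200 ms, last step + 90 ms]; samples outside a trial's
    # recorded span are NaN here and become zeros after standardization.
    from .preprocess import WINDOW_AFTER_MS, WINDOW_BEFORE_MS
    rate_offsets = np.arange(out_offsets[0] - WINDOW_BEFORE_MS,
                             out_offsets[-1] + WINDOW_AFTER_MS + 1, RESAMPLE_MS)

    rates_list, labels_list, aux_acc = [], [], {k: [] for k in
                                               ("theta", "hand", "tau_ext", "tau_flex", "coco")}
    targets_list, groups_list = [], []
    for i, trial in enumerate(trials):
        if not keep[i]:
            continue
        ref = trial.reference
        onset = onsets[i]
        rs = compute_firing_rates(trial.spike_times, config.trial_ms, onset, config.fs)
        kin = process_kinematics(ref.path, arm, manip, config.fs, onset_ms=onset)
        pos = np.round((rate_offsets - rs.offsets_ms[0]) / RESAMPLE_MS).astype(int)
        inside = (pos >= 0) & (pos < rs.rates.shape[1])
        aligned = np.full((rs.rates.shape[0], len(rate_offsets)), np.nan)
        aligned[:, inside] = rs.rates[:, pos[inside]]
        rates_list.append(aligned)
        lab = np.concatenate([_grid_lookup(kin["omega"], kin["offsets_ms"], out_offsets),
                              _grid_lookup(kin["torque"], kin["offsets_ms"], out_offsets)],
                             axis=1)
        labels_list.append(lab)
        aux_acc["theta"].append(_grid_lookup(kin["theta"], kin["offsets_ms"], out_offsets))
        aux_acc["hand"].append(_grid_lookup(kin["hand"], kin["offsets_ms"], out_offsets))
        ms_idx = np.clip(onset + out_offsets, 0, ref.n_samples - 1).astype(int)
        aux_acc["tau_ext"].append(ref.tau_ext[ms_idx])
        aux_acc["tau_flex"].append(ref.tau_flex[ms_idx])
        aux_acc["coco"].append(ref.cocontraction[ms_idx])
        targets_list.append(trial.target)
        groups_list.append(trial.repetition)

    rates = np.stack([np.moveaxis(r, 0, 1) for r in rates_list])   # [B, S, U]
    meta = {"n_sessions": len(sessions), "n_units": population.n_units,
            "trial_ms": config.trial_ms, "pre_onset_ms": config.pre_onset_ms,
            "n_kept": int(keep.sum()), "n_discarded": int((~keep).sum())}
    return DecodingDataset(
        rates, rate_offsets, np.stack(labels_list), out_offsets,
        np.array(targets_list), np.array(groups_list), OUTPUT_NAMES,
        {k: np.stack(v) for k, v in aux_acc.items()},
        population.provenance, selection_reports, meta)
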