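"""Dataset/decoder container round-tripping and run configuration.

Arrays live in HDF5 (hierarchical, attribute-bearing), human-auditable tables
in CSV, configs in YAML, architecture sidecars in JSON.  Every artifact
carries the config hash and seed so the provenance chain is reconstructible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import yaml

from .arm import ArmParameters, ManipulandumParameters
from .datasets import DecodingDataset
from .network import DecoderBlockConfig, DecoderNetwork
from .simulate import NeuronSpec, Session, SyntheticTrial, TaskConfig
from .arm import JointState, TorqueSample

__all__ = ["FORMAT_VERSION", "MigrationError", "default_config", "load_config",
           "config_hash", "save_sessions", "load_sessions", "save_dataset",
           "load_dataset", "save_decoder", "load_decoder"]

FORMAT_VERSION = 1


class MigrationError(RuntimeError):
    """Container written by an incompatible format version."""


# --------------------------------------------------------------------- config
def default_config() -> dict:
    """Run configuration with every constant at its study default."""
    return {
        "task": {
            "n_targets": 8, "target_distance": 0.08, "home": [0.17, -0.15],
            "trial_ms": 1800, "pre_onset_ms": 300, "movement_ms": 600,
            "fs": 1000, "trials_per_target": 10, "neurons_per_session": 2,
            "n_sessions": 10, "endpoint_jitter_m": 0.002,
            "duration_jitter_ms": 30.0, "outlier_fraction": 0.05,
            "cocontraction_amplitude": 0.0, "cocontraction_width_ms": 150.0,
        },
        "arm": {"l1": 0.132, "l2": 0.207, "m1": 0.295, "m2": 0.280},
        "manipulandum": {"masses": [0.565, 0.065], "enabled": True},
        "preprocessing": {
            "rate_lowpass_hz": 7.0, "kinematic_lowpass_hz": 5.0,
            "onset_threshold_m_s2": 0.8, "moving_average_ms": 40,
            "resample_ms": 10, "window_ms": 300, "window_before_ms": 200,
            "heading_dist_mm": 47.0, "trajectory_error_max_mm2": 20.0,
            "speed_r2_min": 0.6, "zscore_mode": "per_unit",
        },
        "architecture": {"name": "single_direction", "block": {}},
        "training": {
            "learning_rate": 1.0e-3, "finetune_learning_rate": 1.0e-4,
            "batch_size": 32, "max_epochs": 1000, "finetune_max_epochs": 100,
            "scheduler_factor": 0.1, "scheduler_patience": 15,
            "early_stop_patience": 20, "val_fraction": 0.2,
            "test_fraction": 0.2, "finetune_fraction": 0.2, "folds": 5,
        },
        "pretrain_targets": [3, 4],   # Targets IV & V (0-based)
        "seed": 0,
    }


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Optional[Union[str, Path]] = None) -> dict:
    """Load a YAML run config, overlaying the study defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = _merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def task_config_from(cfg: dict) -> TaskConfig:
    return TaskConfig(**{k: tuple(v) if k == "home" else v
                         for k, v in cfg["task"].items()})


def arm_from(cfg: dict) -> ArmParameters:
    return ArmParameters(**cfg["arm"])


def manip_from(cfg: dict) -> ManipulandumParameters:
    m = cfg["manipulandum"]
    return ManipulandumParameters(tuple(m["masses"]), m.get("enabled", True))


# ------------------------------------------------------------------- sessions
def save_sessions(path: Union[str, Path], sessions: list, cfg: Optional[dict] = None,
                  seed: Optional[int] = None) -> None:
    """Write simulated sessions: per-trial spike times, kinematics, torques."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "sessions"
        if cfg is not None:
            f.attrs["config_yaml"] = yaml.safe_dump(cfg)
            f.attrs["config_hash"] = config_hash(cfg)
        if seed is not None:
            f.attrs["seed"] = seed
        for s in sessions:
            gs = f.create_group(f"sessions/{s.session_id}")
            gs.attrs["neurons_json"] = json.dumps([vars(n) for n in s.neurons])
            for j, tr in enumerate(s.trials):
                gt = gs.create_group(f"trials/{j}")
                gt.attrs.update({"target": tr.target, "repetition": tr.repetition,
                                 "session_id": tr.session_id, "fs": tr.fs,
                                 "pre_onset_ms": tr.pre_onset_ms})
                gt.create_dataset("hand_path", data=tr.path, compression="gzip")
                kin = np.stack([tr.joints.theta_s, tr.joints.theta_e,
                                tr.joints.omega_s, tr.joints.omega_e,
                                tr.joints.alpha_s, tr.joints.alpha_e], axis=1)
                gt.create_dataset("kinematics", data=kin, compression="gzip")
                gt.create_dataset("torques", data=tr.torques.as_array(), compression="gzip")
                gt.create_dataset("tau_ext", data=tr.tau_ext, compression="gzip")
                gt.create_dataset("tau_flex", data=tr.tau_flex, compression="gzip")
                gt.create_dataset("cocontraction", data=tr.cocontraction, compression="gzip")
                gsp = gt.create_group("spikes")
                for u, st in enumerate(tr.spike_times):
                    gsp.create_dataset(str(u), data=np.asarray(st))


def _check_version(f: h5py.File, kind: str) -> None:
    v = int(f.attrs.get("format_version", -1))
    if v != FORMAT_VERSION:
        raise MigrationError(
            f"{kind} container format version {v} != supported {FORMAT_VERSION}")


def load_sessions(path: Union[str, Path]) -> list:
    with h5py.File(path, "r") as f:
        _check_version(f, "sessions")
        sessions = []
        for sid in sorted(f["sessions"], key=int):
            gs = f[f"sessions/{sid}"]
            neurons = [NeuronSpec(**d) for d in json.loads(gs.attrs["neurons_json"])]
            trials = []
            for j in sorted(gs["trials"], key=int):
                gt = gs[f"trials/{j}"]
                kin = gt["kinematics"][()]
                joints = JointState(*[kin[:, i] for i in range(6)])
                tor = gt["torques"][()]
                tr = SyntheticTrial(
                    int(gt.attrs["target"]), int(gt.attrs["repetition"]),
                    int(gt.attrs["session_id"]), int(gt.attrs["fs"]),
                    int(gt.attrs["pre_onset_ms"]), gt["hand_path"][()],
                    joints, TorqueSample(tor[:, 0], tor[:, 1]),
                    gt["tau_ext"][()], gt["tau_flex"][()],
                    gt["cocontraction"][()],
                    [gt["spikes"][u][()] for u in sorted(gt["spikes"], key=int)])
                trials.append(tr)
            sessions.append(Session(int(sid), neurons, trials))
    return sessions


# -------------------------------------------------------------------- dataset
def save_dataset(path: Union[str, Path], ds: DecodingDataset,
                 stats: Optional[dict] = None, cfg: Optional[dict] = None,
                 seed: Optional[int] = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "dataset"
        f.attrs["fingerprint"] = ds.fingerprint()
        f.attrs["meta_json"] = json.dumps(ds.meta, default=str)
        if cfg is not None:
            f.attrs["config_hash"] = config_hash(cfg)
            f.attrs["config_yaml"] = yaml.safe_dump(cfg)
        if seed is not None:
            f.attrs["seed"] = seed
        f.create_dataset("tensors/X", data=ds.rates, compression="gzip")
        f.create_dataset("tensors/Y", data=ds.labels, compression="gzip")
        f.create_dataset("tensors/rate_offsets_ms", data=ds.rate_offsets_ms)
        f.create_dataset("tensors/output_offsets_ms", data=ds.output_offsets_ms)
        f.create_dataset("tensors/targets", data=ds.targets)
        f.create_dataset("tensors/groups", data=ds.groups)
        f.attrs["outputs_json"] = json.dumps(list(ds.outputs))
        for k, v in ds.aux.items():
            f.create_dataset(f"aux/{k}", data=v, compression="gzip")
        f.attrs["provenance_json"] = json.dumps([list(p) for p in ds.provenance])
        if stats is not None:
            f.create_dataset("norm/mean", data=stats["mean"])
            f.create_dataset("norm/sd", data=stats["sd"])
            f["norm"].attrs["mode"] = stats.get("mode", "per_unit")


def load_dataset(path: Union[str, Path]) -> tuple[DecodingDataset, Optional[dict]]:
    with h5py.File(path, "r") as f:
        _check_version(f, "dataset")
        ds = DecodingDataset(
            f["tensors/X"][()], f["tensors/rate_offsets_ms"][()],
            f["tensors/Y"][()], f["tensors/output_offsets_ms"][()],
            f["tensors/targets"][()], f["tensors/groups"][()],
            tuple(json.loads(f.attrs["outputs_json"])),
            {k: f[f"aux/{k}"][()] for k in f.get("aux", {})},
            [tuple(p) for p in json.loads(f.attrs["provenance_json"])],
            {}, json.loads(f.attrs["meta_json"]))
        stats = None
        if "norm" in f:
            stats = {"mean": f["norm/mean"][()], "sd": f["norm/sd"][()],
                     "mode": f["norm"].attrs["mode"]}
    return ds, stats


# -------------------------------------------------------------------- decoder
def save_decoder(path: Union[str, Path], trained, cfg: Optional[dict] = None) -> None:
    """Checkpoint a TrainedDecoder: weights in HDF5 + JSON architecture sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "decoder"
        f.attrs["architecture_json"] = json.dumps(trained.network.config_dict())
        if cfg is not None:
            f.attrs["config_hash"] = config_hash(cfg)
        for k, v in trained.network.state_dict().items():
            f.create_dataset(f"weights/{k}", data=v)
        f.create_dataset("norm/rate_mean", data=trained.rate_stats["mean"])
        f.create_dataset("norm/rate_sd", data=trained.rate_stats["sd"])
        f["norm"].attrs["mode"] = trained.rate_stats.get("mode", "per_unit")
        f.create_dataset("norm/label_mean", data=trained.label_stats["mean"])
        f.create_dataset("norm/label_sd", data=trained.label_stats["sd"])
        f.attrs["training_json"] = json.dumps(vars(trained.training_config))
        f.attrs["meta_json"] = json.dumps(
            {k: v for k, v in trained.meta.items() if np.isscalar(v) or isinstance(v, str)})
        hist = trained.history
        if len(hist):
            f.create_dataset("history", data=hist.to_numpy())
            f.attrs["history_columns"] = json.dumps(list(hist.columns))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(trained.network.config_dict(), indent=2))


def load_decoder(path: Union[str, Path]):
    from .training import TrainedDecoder, TrainingConfig
    import pandas as pd
    with h5py.File(path, "r") as f:
        _check_version(f, "decoder")
        net = DecoderNetwork.from_config(json.loads(f.attrs["architecture_json"]))
        net.load_state_dict({k: f[f"weights/{k}"][()] for k in f["weights"]})
        rate_stats = {"mean": f["norm/rate_mean"][()], "sd": f["norm/rate_sd"][()],
                      "mode": f["norm"].attrs["mode"]}
        label_stats = {"mean": f["norm/label_mean"][()], "sd": f["norm/label_sd"][()]}
        tcfg = TrainingConfig(**json.loads(f.attrs["training_json"]))
        if "history" in f:
            hist = pd.DataFrame(f["history"][()],
                                columns=json.loads(f.attrs["history_columns"]))
        else:
            hist = pd.DataFrame()
        meta = json.loads(f.attrs["meta_json"])
    return TrainedDecoder(net, rate_stats, label_stats, tcfg, hist, meta)
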