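"""Synthetic center-out reaching sessions with direction-tuned Poisson units.

Emulates the pseudo-population recording design: each daily session records one
or two neurons while the subject repeats planar center-out reaches to eight
targets.  Hand trajectories are minimum-jerk with per-repetition jitter; joint
kinematics and torques are derived with the two-link arm model; each unit is
tuned to one of four directional modules (shoulder-extension, shoulder-flexion,
elbow-extension, elbow-flexion) driven by the lagged, rectified directional
angular velocity or torque; spiking is inhomogeneous Poisson.

Sign convention: "extension" denotes the positive direction of each joint
coordinate, so the directional torques satisfy ``tau_ext - tau_flex = tau``
exactly, with an optional common co-contraction profile added to both sides
(net torque unchanged).

Seed policy: trajectory jitter is keyed by (master seed, target, repetition) —
shared across sessions, so pairing trials of equal repetition index across
sessions yields consistent kinematic labels, the synthetic analogue of "the
monkey executed similar trajectories".  Spiking is keyed by
(master seed, session, target, repetition, neuron).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .arm import (ArmParameters, JointState, ManipulandumParameters, TorqueSample,
                  inverse_dynamics, inverse_kinematics)

__all__ = ["TaskConfig", "NeuronSpec", "SyntheticTrial", "Session",
           "PopulationTrial", "PopulationDataset", "minimum_jerk_trajectory",
           "poisson_spike_train", "synthesize_trial", "generate_session",
           "generate_sessions", "default_neurons", "build_pseudopopulation"]

MODULES = ("shoulder_extension", "shoulder_flexion", "elbow_extension", "elbow_flexion")

_TRAJ_KEY, _SPIKE_KEY = 0, 1


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key)))


@dataclass(frozen=True)
class TaskConfig:
    """Study conditions of the synthetic center-out task."""

    n_targets: int = 8
    target_distance: float = 0.08          # m
    home: tuple[float, float] = (0.17, -0.15)  # m, in shoulder coordinates
    trial_ms: int = 1800
    pre_onset_ms: int = 300
    movement_ms: int = 600
    fs: int = 1000                          # kinematic sampling rate, Hz
    trials_per_target: int = 10
    neurons_per_session: int = 2
    n_sessions: int = 10
    endpoint_jitter_m: float = 0.002
    duration_jitter_ms: float = 30.0
    outlier_fraction: float = 0.05
    cocontraction_amplitude: float = 0.0    # N m
    cocontraction_width_ms: float = 150.0

    def __post_init__(self) -> None:
        if not self.trial_ms > self.pre_onset_ms:
            raise ValueError("trial duration must exceed the pre-onset period")
        if self.fs <= 0 or self.n_targets < 1 or self.trials_per_target < 1:
            raise ValueError("rates and counts must be positive")

    def target_position(self, target: int) -> np.ndarray:
        ang = 2.0 * np.pi * target / self.n_targets
        return np.asarray(self.home) + self.target_distance * np.array([np.cos(ang), np.sin(ang)])


@dataclass(frozen=True)
class NeuronSpec:
    """Tuning of one synthetic unit.

    ``module`` selects joint and direction; ``drive`` selects the encoded
    variable (directional angular velocity in rad/s or directional torque in
    N m); the firing rate is ``baseline + gain * drive(t + lag)`` — units lead
    the movement by ``lag_ms`` — plus optional mixing toward the opposite
    direction.
    """

    module: str = "shoulder_extension"
    drive: str = "angular_velocity"
    baseline_hz: float = 5.0
    gain: float = 40.0
    lag_ms: float = 100.0
    mix: float = 0.0

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise ValueError(f"module must be one of {MODULES}")
        if self.drive not in ("angular_velocity", "torque"):
            raise ValueError("drive must be 'angular_velocity' or 'torque'")
        if self.baseline_hz < 0 or self.gain < 0:
            raise ValueError("baseline and gain must be non-negative")


@dataclass
class SyntheticTrial:
    """One synthetic reach with full ground truth."""

    target: int
    repetition: int
    session_id: int
    fs: int
    pre_onset_ms: int
    path: np.ndarray                 # [n, 2] hand position, m
    joints: JointState               # angle/velocity/acceleration series
    torques: TorqueSample            # net torques, N m
    tau_ext: np.ndarray              # [n, 2] directional torques >= 0
    tau_flex: np.ndarray             # [n, 2]
    cocontraction: np.ndarray        # [n] commanded co-contraction, N m
    spike_times: list = field(default_factory=list)   # per neuron, seconds

    @property
    def n_samples(self) -> int:
        return self.path.shape[0]


@dataclass
class Session:
    session_id: int
    neurons: list
    trials: list                      # SyntheticTrial, ordered (target, repetition)

    def trial(self, target: int, repetition: int) -> Optional[SyntheticTrial]:
        for t in self.trials:
            if t.target == target and t.repetition == repetition:
                return t
        return None


def minimum_jerk_trajectory(start, goal, duration_ms: float, fs: int = 1000) -> np.ndarray:
    """Straight-line minimum-jerk path sampled at ``fs``; includes both endpoints.

    Zero velocity and acceleration at both ends; peak speed 1.875 d/T.
    """
    if duration_ms <= 0:
        raise ValueError("movement duration must be positive")
    start = np.asarray(start, dtype=float)
    goal = np.asarray(goal, dtype=float)
    # n intervals spanning exactly `duration_ms`, both endpoints included
    n = max(int(round(duration_ms * fs / 1000.0)), 1) + 1
    tau = np.linspace(0.0, 1.0, n)[:, None]
    s = 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5
    return start + s * (goal - start)


def poisson_spike_train(rate_hz: np.ndarray, seed, fs: int = 1000) -> np.ndarray:
    """Inhomogeneous Poisson spikes by per-bin thinning.

    ``rate_hz`` is the instantaneous rate on a 1/fs grid; returns spike times
    in seconds (bin centres).  Reproducible under a seed or Generator.
    """
    rate_hz = np.asarray(rate_hz, dtype=float)
    if np.any(rate_hz < 0):
        raise ValueError("firing rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.minimum(rate_hz / fs, 1.0)
    hits = rng.random(rate_hz.shape) < p
    return (np.flatnonzero(hits) + 0.5) / fs


def _cocontraction_profile(n: int, onset_ms: int, movement_ms: int,
                           amplitude: float, width_ms: float, fs: int) -> np.ndarray:
    if amplitude <= 0:
        return np.zeros(n)
    t = np.arange(n) * 1000.0 / fs
    centre = onset_ms + movement_ms
    return amplitude * np.exp(-0.5 * ((t - centre) / width_ms) ** 2)


def _directional_drive(trial: SyntheticTrial, spec: NeuronSpec) -> np.ndarray:
    joint = 0 if spec.module.startswith("shoulder") else 1
    ext = spec.module.endswith("extension")
    if spec.drive == "angular_velocity":
        omega = trial.joints.omega_s if joint == 0 else trial.joints.omega_e
        main = np.maximum(omega, 0.0) if ext else np.maximum(-omega, 0.0)
        opp = np.maximum(-omega, 0.0) if ext else np.maximum(omega, 0.0)
    else:
        main = trial.tau_ext[:, joint] if ext else trial.tau_flex[:, joint]
        opp = trial.tau_flex[:, joint] if ext else trial.tau_ext[:, joint]
    return main, opp


def neuron_rate(trial: SyntheticTrial, spec: NeuronSpec) -> np.ndarray:
    """Instantaneous firing-rate profile (Hz) of a unit for one trial."""
    main, opp = _directional_drive(trial, spec)
    shift = int(round(spec.lag_ms * trial.fs / 1000.0))

    def lead(x: np.ndarray) -> np.ndarray:
        if shift == 0:
            return x
        return np.concatenate([x[shift:], np.full(shift, x[-1])])

    rate = spec.baseline_hz + spec.gain * lead(main)
    if spec.mix:
        rate = rate + spec.mix * spec.gain * lead(opp)
    return np.maximum(rate, 0.0)


def synthesize_trial(target: int, config: TaskConfig,
                     arm: ArmParameters = ArmParameters(),
                     manip: Optional[ManipulandumParameters] = None,
                     neurons: Sequence[NeuronSpec] = (),
                     cocontraction_amplitude: Optional[float] = None,
                     trial_seed: int = 0, repetition: int = 0, session_id: int = 0,
                     trajectory_seed: Optional[int] = None,
                     master_seed: Optional[int] = None) -> SyntheticTrial:
    """Generate one reach: trajectory, joint/torque labels and spike trains.

    Trajectory jitter uses ``trajectory_seed`` (falling back to ``trial_seed``)
    so that different sessions can share identical kinematics per
    (target, repetition); spike noise uses ``trial_seed``.  When
    ``master_seed`` is given both seeds are derived per the module seed policy.
    """
    if target >= config.n_targets:
        raise ValueError(f"target {target} out of range for {config.n_targets} targets")
    if manip is None:
        manip = ManipulandumParameters()
    if cocontraction_amplitude is None:
        cocontraction_amplitude = config.cocontraction_amplitude
    if master_seed is not None:
        traj_rng = _rng(master_seed, _TRAJ_KEY, target, repetition)
        spike_rng = _rng(master_seed, _SPIKE_KEY, session_id, target, repetition)
    else:
        traj_rng = np.random.default_rng(
            trial_seed if trajectory_seed is None else trajectory_seed)
        spike_rng = np.random.default_rng(np.random.SeedSequence(int(trial_seed), spawn_key=(1,)))

    fs, n = config.fs, int(round(config.trial_ms * config.fs / 1000.0))
    pre = int(round(config.pre_onset_ms * config.fs / 1000.0))
    home = np.asarray(config.home, dtype=float)
    goal = config.target_position(target) + traj_rng.normal(0.0, config.endpoint_jitter_m, 2)
    if config.outlier_fraction > 0 and traj_rng.random() < config.outlier_fraction:
        # deviant reach: heading rotated well away from the target direction
        ang = np.deg2rad(np.sign(traj_rng.random() - 0.5) * (30.0 + 20.0 * traj_rng.random()))
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        goal = home + rot @ (goal - home)
    dur = config.movement_ms + traj_rng.normal(0.0, config.duration_jitter_ms)
    dur = float(np.clip(dur, 200.0, config.trial_ms - config.pre_onset_ms - 100.0))
    reach = minimum_jerk_trajectory(home, goal, dur, fs)
    path = np.concatenate([np.tile(home, (pre, 1)), reach,
                           np.tile(goal, (n - pre - reach.shape[0], 1))])[:n]

    ts, te = inverse_kinematics(path[:, 0], path[:, 1], arm)
    ws = np.gradient(ts) * fs
    we = np.gradient(te) * fs
    als = np.gradient(ws) * fs
    ale = np.gradient(we) * fs
    joints = JointState(ts, te, ws, we, als, ale)
    torques = inverse_dynamics(joints, arm, manip)
    tor = torques.as_array()
    coco = _cocontraction_profile(n, config.pre_onset_ms, int(round(dur)),
                                  cocontraction_amplitude,
                                  config.cocontraction_width_ms, fs)
    tau_ext = np.maximum(tor, 0.0) + coco[:, None]
    tau_flex = np.maximum(-tor, 0.0) + coco[:, None]

    trial = SyntheticTrial(target, repetition, session_id, fs, config.pre_onset_ms,
                           path, joints, torques, tau_ext, tau_flex, coco)
    for spec in neurons:
        rate = neuron_rate(trial, spec)
        trial.spike_times.append(poisson_spike_train(rate, spike_rng, fs))
    return trial


def default_neurons(n: int, seed: int = 0, drives: tuple = ("angular_velocity", "torque")) -> list[NeuronSpec]:
    """A mixed bank of units cycling over the four directional modules.

    Gains give peak modulations of roughly 40-80 Hz over a 2-8 Hz baseline for
    the default reach amplitude; lags centre on a 100 ms neural lead.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        module = MODULES[i % 4]
        drive = drives[(i // 4) % len(drives)]
        base_gain = 40.0 if drive == "angular_velocity" else 150.0
        specs.append(NeuronSpec(
            module=module, drive=drive,
            baseline_hz=float(rng.uniform(2.0, 8.0)),
            gain=float(base_gain * rng.lognormal(0.0, 0.25)),
            lag_ms=float(np.clip(rng.normal(100.0, 20.0), 0.0, 180.0)),
            mix=0.0))
    return specs


def generate_session(session_id: int, config: TaskConfig,
                     arm: ArmParameters = ArmParameters(),
                     manip: Optional[ManipulandumParameters] = None,
                     neurons: Optional[Sequence[NeuronSpec]] = None,
                     master_seed: int = 0) -> Session:
    if neurons is None:
        neurons = default_neurons(config.neurons_per_session,
                                  seed=int(_rng(master_seed, 2, session_id).integers(2 ** 31)))
    trials = []
    for target in range(config.n_targets):
        for rep in range(config.trials_per_target):
            trials.append(synthesize_trial(
                target, config, arm, manip, neurons,
                repetition=rep, session_id=session_id, master_seed=master_seed))
    return Session(session_id, list(neurons), trials)


def generate_sessions(config: TaskConfig, arm: ArmParameters = ArmParameters(),
                      manip: Optional[ManipulandumParameters] = None,
                      master_seed: int = 0) -> list[Session]:
    return [generate_session(s, config, arm, manip, master_seed=master_seed)
            for s in range(config.n_sessions)]


@dataclass
class PopulationTrial:
    """Trial-matched pseudo-population trial: all units' spikes + shared kinematics."""

    target: int
    repetition: int
    reference: SyntheticTrial        # kinematics source
    spike_times: list                # length = total units
    provenance: list                 # (session_id, neuron_index) per unit


@dataclass
class PopulationDataset:
    trials: list
    provenance: list                 # (session_id, neuron_index) per unit column
    n_units: int

    def targets(self) -> np.ndarray:
        return np.array([t.target for t in self.trials])


def build_pseudopopulation(sessions: Sequence[Session]) -> PopulationDataset:
    """Combine units across sessions by matching repetition indices per target.

    Every session must contain every target; the paired repetition range per
    target is the intersection across sessions.  Kinematic labels come from the
    first session's trial (identical across sessions under the shared
    trajectory-seed policy).
    """
    targets = sorted({t.target for s in sessions for t in s.trials})
    for s in sessions:
        present = {t.target for t in s.trials}
        missing = [k for k in targets if k not in present]
        if missing:
            raise ValueError(f"session {s.session_id} missing target(s) {missing}")
    provenance = [(s.session_id, j) for s in sessions for j in range(len(s.neurons))]
    trials = []
    for target in targets:
        reps = None
        for s in sessions:
            have = {t.repetition for t in s.trials if t.target == target}
            reps = have if reps is None else reps & have
        for rep in sorted(reps):
            spikes, ref = [], None
            for s in sessions:
                tr = s.trial(target, rep)
                if ref is None:
                    ref = tr
                spikes.extend(tr.spike_times)
            trials.append(PopulationTrial(target, rep, ref, spikes, list(provenance)))
    return PopulationDataset(trials, provenance, len(provenance))
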