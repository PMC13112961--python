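"""Spike-rate and kinematic preprocessing, trial selection, and tensorisation.

Pipeline (offline, so all filters are applied forward-backward, zero-phase):

* firing rates — per 1-ms bin the inverse inter-spike interval of the spikes
  bracketing the bin, low-passed with a 4th-order Butterworth at 7 Hz, smoothed
  with a 40-ms moving average, resampled on a 10-ms grid aligned to movement
  onset, clipped at zero;
* kinematics — joint angles by inverse kinematics, angular velocities and
  accelerations by central differences low-passed at 5 Hz, torques by inverse
  dynamics with the manipulandum coupling, downsampled to 100 Hz;
* movement onset — first time the hand's tangential acceleration reaches
  0.8 m/s^2;
* trial selection — heading angle at 47 mm from home, K-means (k=3) clustering,
  the largest cluster is the reference; a trial is kept iff its trajectory
  error s < 20 mm^2 and its speed-profile R^2 > 0.6 against the reference;
* z-scoring per unit over the training partition (the literal printed variant
  — cross-unit mean, per-unit sigma — is available as ``mode="printed"``);
* sliding-window tensorisation into ``[B, T, C, L]`` with a 300-ms window
  (200 ms before each motion step, 100 ms after) on the 10-ms grid (L = 30).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from sklearn.cluster import KMeans

from .arm import (ArmParameters, JointState, ManipulandumParameters,
                  inverse_dynamics, inverse_kinematics)

__all__ = ["RateSeries", "TrialSelectionReport", "WindowedTensor", "NoOnsetError",
           "compute_firing_rates", "detect_onset", "process_kinematics",
           "select_trials", "zscore_units", "window_spikes",
           "WINDOW_BEFORE_MS", "WINDOW_AFTER_MS", "RESAMPLE_MS"]

WINDOW_BEFORE_MS = 200
WINDOW_AFTER_MS = 90        # last lag sample sits at +90 ms; the window spans 300 ms
RESAMPLE_MS = 10
CENTER_LAG = WINDOW_BEFORE_MS // RESAMPLE_MS   # lag index holding the motion step itself


class NoOnsetError(ValueError):
    """Tangential acceleration never crossed the onset threshold."""


@dataclass
class RateSeries:
    """Per-unit firing rates (Hz) on a uniform grid aligned to movement onset."""

    rates: np.ndarray          # [n_units, n_samples]
    offsets_ms: np.ndarray     # [n_samples], time relative to onset
    interval_ms: int = RESAMPLE_MS


def _zero_phase_lowpass(x: np.ndarray, cutoff_hz: float, fs: float, order: int = 4,
                        axis: int = -1) -> np.ndarray:
    b, a = butter(order, cutoff_hz / (fs / 2.0))
    return filtfilt(b, a, x, axis=axis)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), -1, x)


def _onset_grid(n_samples: int, onset_ms: int, step: int) -> np.ndarray:
    """Indices of a ``step``-ms grid over [0, n) containing ``onset_ms`` exactly."""
    phase = int(onset_ms) % step
    return np.arange(phase, n_samples, step)


def compute_firing_rates(spike_times: Sequence[np.ndarray], trial_ms: int,
                         onset_ms: int, fs: int = 1000, lowpass_hz: float = 7.0,
                         ma_ms: int = 40, resample_ms: int = RESAMPLE_MS) -> RateSeries:
    """Inverse-ISI firing rates, filtered, averaged and resampled.

    Empty or single-spike trains yield all-zero series.  The rate in each 1-ms
    bin is the inverse interval of the spikes immediately before and after the
    bin centre (zero outside the recorded spike span).
    """
    n = int(round(trial_ms * fs / 1000.0))
    centres = (np.arange(n) + 0.5) / fs
    raw = np.zeros((len(spike_times), n))
    for u, spikes in enumerate(spike_times):
        spikes = np.sort(np.asarray(spikes, dtype=float))
        if spikes.size < 2:
            continue
        idx = np.searchsorted(spikes, centres)
        ok = (idx >= 1) & (idx <= spikes.size - 1)
        isi = spikes[idx[ok]] - spikes[idx[ok] - 1]
        raw[u, ok] = 1.0 / isi
    smooth = _zero_phase_lowpass(raw, lowpass_hz, fs)
    smooth = _moving_average(smooth, int(round(ma_ms * fs / 1000.0)))
    smooth = np.maximum(smooth, 0.0)
    idx = _onset_grid(n, onset_ms, int(round(resample_ms * fs / 1000.0)))
    return RateSeries(smooth[:, idx], idx * 1000.0 / fs - onset_ms, resample_ms)


def detect_onset(path: np.ndarray, fs: int = 1000, threshold: float = 0.8) -> int:
    """Movement onset (ms): first sample with tangential acceleration >= threshold.

    Tangential acceleration is the time derivative of hand speed.
    """
    path = np.asarray(path, dtype=float)
    v = np.gradient(path, axis=0) * fs
    speed = np.hypot(v[:, 0], v[:, 1])
    tacc = np.gradient(speed) * fs
    hits = np.flatnonzero(tacc >= threshold)
    if hits.size == 0:
        raise NoOnsetError(
            f"tangential acceleration never reached {threshold} m/s^2 "
            f"(max {tacc.max():.3g})")
    return int(round(hits[0] * 1000.0 / fs))


def process_kinematics(path: np.ndarray, arm: ArmParameters = ArmParameters(),
                       manip: Optional[ManipulandumParameters] = None,
                       fs: int = 1000, lowpass_hz: float = 5.0,
                       onset_ms: int = 0, resample_ms: int = RESAMPLE_MS) -> dict:
    """Joint angle/velocity/torque labels on the onset-aligned 10-ms grid.

    Returns a dict with per-sample arrays ``offsets_ms``, ``theta`` [n,2],
    ``omega`` [n,2], ``torque`` [n,2] and the resampled hand path.
    Raises a reachability error naming the first offending sample if the path
    leaves the arm's workspace.
    """
    path = np.asarray(path, dtype=float)
    if manip is None:
        manip = ManipulandumParameters()
    ts, te = inverse_kinematics(path[:, 0], path[:, 1], arm)
    theta = np.stack([ts, te], axis=1)
    omega = _zero_phase_lowpass(np.gradient(theta, axis=0) * fs, lowpass_hz, fs, axis=0)
    alpha = _zero_phase_lowpass(np.gradient(omega, axis=0) * fs, lowpass_hz, fs, axis=0)
    state = JointState(ts, te, omega[:, 0], omega[:, 1], alpha[:, 0], alpha[:, 1])
    torque = inverse_dynamics(state, arm, manip).as_array()
    idx = _onset_grid(path.shape[0], onset_ms, int(round(resample_ms * fs / 1000.0)))
    return {
        "offsets_ms": idx * 1000.0 / fs - onset_ms,
        "theta": theta[idx], "omega": omega[idx], "torque": torque[idx],
        "alpha": alpha[idx], "hand": path[idx],
    }


@dataclass
class TrialSelectionReport:
    """Per-trial selection outcome plus the reference trajectory."""

    table: pd.DataFrame                    # trial, cluster, s_mm2, r2, keep, reason
    reference: dict = field(default_factory=dict)   # x, y, speed, mean_onset_ms
    warning: Optional[str] = None

    @property
    def kept(self) -> np.ndarray:
        return self.table.index[self.table["keep"]].to_numpy()


def _heading_angle(path: np.ndarray, home: np.ndarray, dist_m: float) -> Optional[float]:
    d = np.hypot(path[:, 0] - home[0], path[:, 1] - home[1])
    hits = np.flatnonzero(d >= dist_m)
    if hits.size == 0:
        return None
    p = path[hits[0]] - home
    return float(np.arctan2(p[1], p[0]))


def select_trials(paths: Sequence[np.ndarray], onsets: Sequence[int],
                  home: Optional[np.ndarray] = None, fs: int = 1000,
                  heading_dist_mm: float = 47.0, n_clusters: int = 3,
                  s_max_mm2: float = 20.0, r2_min: float = 0.6,
                  window_samples: int = 1500, seed: int = 0) -> TrialSelectionReport:
    """Discard trials deviating from the per-target reference trajectory.

    Trials are clustered (k=3) on the heading angle at 47 mm from home; the
    largest cluster defines the reference (ties broken by sorted centroid
    order).  After aligning each trial's onset to the mean onset, the
    trajectory error s (mm^2, Eq-style summed squared deviation over a 1500-ms
    window divided by its length) and the speed-profile R^2 against the
    reference decide retention: keep iff s < 20 and R^2 > 0.6.
    """
    n_trials = len(paths)
    if home is None:
        home = np.asarray(paths[0][0], dtype=float)
    angles = [_heading_angle(p, home, heading_dist_mm / 1000.0) for p in paths]
    valid = np.array([a is not None for a in angles])
    table = pd.DataFrame({
        "cluster": -1, "s_mm2": np.nan, "r2": np.nan,
        "keep": False, "reason": "",
    }, index=pd.RangeIndex(n_trials, name="trial"))
    table.loc[~valid, "reason"] = "never_reached_heading_distance"

    warning = None
    vidx = np.flatnonzero(valid)
    if vidx.size < max(n_clusters, 3):
        # too few trials to cluster: retain everything, flagged
        warning = "fewer than 3 clusterable trials; all retained without selection"
        table.loc[vidx, "keep"] = True
        table.loc[vidx, "reason"] = "retained_without_selection"
        return TrialSelectionReport(table, {}, warning)

    ang = np.array([angles[i] for i in vidx])[:, None]
    km = KMeans(n_clusters=n_clusters, n_init=50, random_state=seed).fit(ang)
    labels = km.labels_
    sizes = np.bincount(labels, minlength=n_clusters)
    best = sizes.max()
    tied = np.flatnonzero(sizes == best)
    # deterministic tie-break: among largest clusters, lowest centroid first
    ref_cluster = tied[np.argmin(km.cluster_centers_[tied, 0])]
    table.loc[vidx, "cluster"] = labels

    mean_onset = int(round(np.mean([onsets[i] for i in vidx])))

    def aligned(i: int) -> np.ndarray:
        p = paths[i]
        start = int(onsets[i] * fs / 1000.0)
        seg = p[start:start + window_samples]
        if seg.shape[0] < window_samples:   # hold the last sample if short
            pad = np.tile(seg[-1], (window_samples - seg.shape[0], 1))
            seg = np.concatenate([seg, pad])
        return seg

    ref_members = vidx[labels == ref_cluster]
    ref_stack = np.stack([aligned(i) for i in ref_members])
    ref_xy = ref_stack.mean(axis=0)
    speeds = {i: np.hypot(*((np.gradient(aligned(i), axis=0) * fs).T)) for i in vidx}
    ref_speed = np.stack([speeds[i] for i in ref_members]).mean(axis=0)
    ref_speed_mean = ref_speed.mean()

    for i in vidx:
        seg = aligned(i)
        d_mm = (seg - ref_xy) * 1000.0
        s_i = float((d_mm ** 2).sum() / window_samples)
        v = speeds[i]
        denom = float(((v - ref_speed_mean) ** 2).sum())
        r2 = 1.0 - float(((v - ref_speed) ** 2).sum()) / denom if denom > 0 else 1.0
        keep = (s_i < s_max_mm2) and (r2 > r2_min)
        table.loc[i, ["s_mm2", "r2", "keep"]] = s_i, r2, keep
        if not keep:
            table.loc[i, "reason"] = ("trajectory_error" if s_i >= s_max_mm2
                                      else "speed_profile_r2")
    reference = {"x": ref_xy[:, 0], "y": ref_xy[:, 1], "speed": ref_speed,
                 "mean_onset_ms": mean_onset, "cluster": int(ref_cluster)}
    return TrialSelectionReport(table, reference, warning)


def zscore_units(rates: np.ndarray, train_index: Optional[np.ndarray] = None,
                 mode: str = "per_unit", stats: Optional[dict] = None):
    """Standardise per-unit firing rates using training-partition statistics.

    ``rates`` is ``[B, S, U]`` (trials x samples x units).  Statistics (mean and
    standard deviation per unit) are fit on ``train_index`` trials only and
    returned for reuse; pass ``stats`` to apply previously fitted statistics.
    Units with zero variance become all-zero channels.  ``mode="printed"``
    reproduces the literal printed normalisation (cross-unit mean at each time
    point, per-unit sigma).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 3:
        raise ValueError("rates must be [trials, samples, units]")
    if stats is None:
        fit = rates if train_index is None else rates[np.asarray(train_index)]
        # NaN samples mark coverage padding and are excluded from the statistics
        mean = np.nanmean(fit, axis=(0, 1))
        sd = np.nanstd(fit, axis=(0, 1))
        stats = {"mean": mean, "sd": sd, "mode": mode}
    else:
        if stats["mean"].shape[0] != rates.shape[2]:
            raise ValueError(
                f"unit count mismatch: stats for {stats['mean'].shape[0]} units, "
                f"data has {rates.shape[2]}")
        mode = stats.get("mode", mode)
    sd = stats["sd"]
    safe_sd = np.where(sd > 0, sd, 1.0)
    if mode == "per_unit":
        z = (rates - stats["mean"]) / safe_sd
    elif mode == "printed":
        z = (rates - np.nanmean(rates, axis=2, keepdims=True)) / safe_sd
    else:
        raise ValueError(f"unknown z-score mode {mode!r}")
    z = np.where(sd > 0, z, 0.0)
    z = np.nan_to_num(z, nan=0.0)   # zero-pad standardized coverage gaps
    return z, stats


@dataclass
class WindowedTensor:
    """Sliding-window decoder input with its padded series backing store.

    ``series`` has shape ``[B, T + L - 1, C]`` where sample ``t + k`` holds the
    standardized rate at lag offset ``(k - 20) * 10`` ms from output step ``t``;
    ``tensor`` is a zero-copy strided view ``[B, T, C, L]``.
    """

    series: np.ndarray
    n_steps: int
    lag_samples: int = 30
    stats: Optional[dict] = None
    n_padded: int = 0
    padded: bool = False

    @property
    def tensor(self) -> np.ndarray:
        win = np.lib.stride_tricks.sliding_window_view(
            self.series, self.lag_samples, axis=1)      # [B, T, C, L]
        return win

    @property
    def linear(self) -> np.ndarray:
        """Flattened ``[(B*T) x C]`` view at the window-centre lag."""
        B = self.series.shape[0]
        centre = self.series[:, CENTER_LAG:CENTER_LAG + self.n_steps, :]
        return centre.reshape(B * self.n_steps, -1)


def window_spikes(standardized: np.ndarray, offsets_ms: np.ndarray,
                  output_offsets_ms: np.ndarray, stats: Optional[dict] = None,
                  lag_samples: int = 30, allow_padding: bool = True) -> WindowedTensor:
    """Tensorise standardized rates into the decoder's windowed input.

    ``standardized`` is ``[B, S, U]`` on the grid ``offsets_ms``;
    ``output_offsets_ms`` (length T, same 10-ms spacing) selects the motion
    steps.  For each step t the lag axis holds the 30 consecutive samples
    covering [t-200 ms, t+90 ms].  Samples outside the recorded span are
    zero-padded (flagged) when ``allow_padding``; otherwise a coverage error.
    """
    standardized = np.asarray(standardized, dtype=float)
    B, S, U = standardized.shape
    step = RESAMPLE_MS
    T = len(output_offsets_ms)
    first_needed = output_offsets_ms[0] - WINDOW_BEFORE_MS
    # index into the recorded grid for each required series sample
    need = first_needed + np.arange(T + lag_samples - 1) * step
    pos = np.round((need - offsets_ms[0]) / step).astype(int)
    inside = (pos >= 0) & (pos < S)
    n_pad = int((~inside).sum())
    if n_pad and not allow_padding:
        raise ValueError(
            f"rate series does not cover [{need[0]}, {need[-1]}] ms around onset "
            f"({n_pad} missing samples) and padding is disabled")
    series = np.zeros((B, T + lag_samples - 1, U))
    series[:, inside, :] = standardized[:, pos[inside], :]
    return WindowedTensor(series, T, lag_samples, stats, n_pad, bool(n_pad))
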