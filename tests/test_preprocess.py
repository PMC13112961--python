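"""Spike-rate pipeline, onset detection, trial selection, z-scoring, windowing."""

import numpy as np
import pandas as pd
import pytest

from sdnet.preprocess import (NoOnsetError, compute_firing_rates, detect_onset,
                              process_kinematics, select_trials, window_spikes,
                              zscore_units)
from sdnet.simulate import minimum_jerk_trajectory


class TestFiringRates:
    def test_empty_and_single_spike_trains_are_silent(self):
        rs = compute_firing_rates([np.array([]), np.array([0.5])], 1000, 300)
        assert np.allclose(rs.rates, 0.0)

    def test_periodic_train_recovers_plateau_rate(self):
        # perfectly periodic 100 Hz: ISI = 10 ms, rate plateau ~ 100 Hz
        spikes = np.arange(0.005, 2.0, 0.01)
        rs = compute_firing_rates([spikes], 2000, 300)
        mid = rs.rates[0, 40:-40]
        assert np.all(np.abs(mid - 100.0) / 100.0 < 0.02)

    def test_rate_integral_conserves_spike_count(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 1.5, 30))   # ~20 Hz over 1.5 s
        rs = compute_firing_rates([spikes], 1500, 300)
        integral = rs.rates[0].sum() * 0.010
        # the inverse-ISI rate integrates to the number of intervals (count - 1)
        assert abs(integral - (len(spikes) - 1)) / (len(spikes) - 1) < 0.10

    def test_rates_clipped_non_negative(self):
        spikes = np.array([0.1, 0.11, 0.5, 0.9, 0.91])
        rs = compute_firing_rates([spikes], 1000, 300)
        assert rs.rates.min() >= 0.0

    def test_grid_aligned_on_onset(self):
        rs = compute_firing_rates([np.arange(0.0, 1.0, 0.02)], 1000, onset_ms=307)
        assert 0.0 in rs.offsets_ms          # one sample exactly at onset
        assert np.all(np.diff(rs.offsets_ms) == 10)


class TestOnset:
    def test_stationary_trial_has_no_onset(self):
        path = np.tile([0.1, 0.2], (600, 1))
        with pytest.raises(NoOnsetError):
            detect_onset(path)

    def test_min_jerk_onset_near_analytic_crossing(self):
        # 8 cm / 600 ms reach after 300 ms of rest
        reach = minimum_jerk_trajectory([0.1, 0.0], [0.18, 0.0], 600)
        path = np.concatenate([np.tile([0.1, 0.0], (300, 1)), reach])
        onset = detect_onset(path, threshold=0.8)
        # analytic: |a(t)| = (d/T^2)(60 s - 180 s^2 + 120 s^3), first crossing of 0.8
        s = np.linspace(0, 1, 60001)
        acc = 0.08 / 0.6 ** 2 * (60 * s - 180 * s ** 2 + 120 * s ** 3)
        analytic = 300 + 600 * s[np.argmax(acc >= 0.8)]
        assert abs(onset - analytic) <= 10

    def test_threshold_monotonicity(self):
        reach = minimum_jerk_trajectory([0.1, 0.0], [0.18, 0.0], 600)
        path = np.concatenate([np.tile([0.1, 0.0], (300, 1)), reach])
        onsets = [detect_onset(path, threshold=th) for th in (0.4, 0.8, 1.2)]
        assert onsets == sorted(onsets)


class TestKinematicLabels:
    def test_constant_path_zero_velocity_and_torque(self, arm):
        path = np.tile([0.15, -0.1], (1200, 1))
        kin = process_kinematics(path, arm, onset_ms=300)
        assert np.allclose(kin["omega"], 0.0, atol=1e-12)
        assert np.allclose(kin["torque"], 0.0, atol=1e-12)

    def test_decimation_contract(self, arm):
        path = np.tile([0.15, -0.1], (1205, 1))
        kin = process_kinematics(path, arm, onset_ms=0)
        assert len(kin["offsets_ms"]) == int(np.ceil(1205 / 10))

    def test_velocity_recovery_on_smooth_reach(self, arm):
        from sdnet.arm import inverse_kinematics
        reach = minimum_jerk_trajectory([0.15, -0.1], [0.21, -0.04], 600)
        path = np.concatenate([np.tile([0.15, -0.1], (300, 1)), reach,
                               np.tile([0.21, -0.04], (300, 1))])
        kin = process_kinematics(path, arm, onset_ms=300)
        ts, te = inverse_kinematics(path[:, 0], path[:, 1], arm)
        w_true = np.stack([np.gradient(ts), np.gradient(te)], 1) * 1000
        idx = (kin["offsets_ms"] + 300).astype(int)
        err = kin["omega"] - w_true[idx]
        assert np.sqrt((err ** 2).mean()) < 0.02 * np.abs(w_true).max()

    def test_unreachable_sample_names_index(self, arm):
        path = np.tile([0.15, -0.1], (400, 1))
        path[250:] = [1.0, 1.0]
        with pytest.raises(Exception, match="index 250"):
            process_kinematics(path, arm, onset_ms=0)


def _reach_bundle(n_trials, angle_deg, seed=0, outlier=None):
    """n similar reaches at angle_deg (plus an optional deviant one)."""
    rng = np.random.default_rng(seed)
    paths, onsets = [], []
    for i in range(n_trials):
        ang = np.deg2rad(angle_deg if outlier is None or i != outlier
                         else -angle_deg)   # reflected across the x axis
        goal = np.array([0.15, -0.1]) + 0.08 * np.array([np.cos(ang), np.sin(ang)])
        goal += rng.normal(0, 5e-4, 2)
        reach = minimum_jerk_trajectory([0.15, -0.1], goal, 600)
        path = np.concatenate([np.tile([0.15, -0.1], (300, 1)), reach,
                               np.tile(goal, (1000, 1))])[:1800]
        paths.append(path)
        onsets.append(detect_onset(path))
    return paths, onsets


class TestTrialSelection:
    def test_identical_trials_all_kept_with_perfect_scores(self):
        paths, onsets = _reach_bundle(9, 40.0)
        rep = select_trials(paths, onsets)
        assert rep.table["keep"].all()
        assert rep.table["s_mm2"].max() < 5.0   # well under the 20 mm^2 gate
        assert rep.table["r2"].min() > 0.99

    def test_reflected_outlier_discarded(self):
        paths, onsets = _reach_bundle(10, 40.0, outlier=6)
        rep = select_trials(paths, onsets)
        assert not rep.table.loc[6, "keep"]
        assert rep.table.drop(6)["keep"].all()
        # brute-force trajectory error of the deviant trial is far over threshold
        assert rep.table.loc[6, "s_mm2"] > 20.0

    def test_selection_permutation_invariant(self):
        paths, onsets = _reach_bundle(10, 40.0, outlier=3)
        keep0 = select_trials(paths, onsets).table["keep"].to_numpy()
        perm = np.random.default_rng(1).permutation(10)
        keep1 = select_trials([paths[i] for i in perm],
                              [onsets[i] for i in perm]).table["keep"].to_numpy()
        assert np.array_equal(keep0[perm], keep1)

    def test_short_reach_gets_reason_code(self):
        paths, onsets = _reach_bundle(8, 40.0)
        paths.append(np.tile([0.15, -0.1], (1800, 1)) +
                     np.random.default_rng(0).normal(0, 1e-4, (1800, 2)))
        onsets.append(onsets[0])
        rep = select_trials(paths, onsets)
        assert rep.table.loc[8, "reason"] == "never_reached_heading_distance"
        assert not rep.table.loc[8, "keep"]

    def test_too_few_trials_retained_with_warning(self):
        paths, onsets = _reach_bundle(2, 30.0)
        rep = select_trials(paths, onsets)
        assert rep.warning is not None
        assert rep.table["keep"].all()


class TestZScore:
    def test_fit_partition_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        r = rng.gamma(2.0, 10.0, size=(6, 50, 4))
        z, stats = zscore_units(r, train_index=np.arange(4))
        fit = z[:4].reshape(-1, 4)
        assert np.allclose(fit.mean(0), 0.0, atol=1e-12)
        assert np.allclose(fit.std(0), 1.0, atol=1e-12)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(1)
        r = rng.normal(size=(3, 40, 5))
        z1, _ = zscore_units(r)
        z2, _ = zscore_units(z1)
        assert np.allclose(z1, z2, atol=1e-12)

    def test_constant_unit_becomes_zero_channel(self):
        r = np.ones((4, 30, 2))
        r[..., 1] = np.random.default_rng(0).normal(size=(4, 30))
        z, _ = zscore_units(r)
        assert np.allclose(z[..., 0], 0.0)
        assert np.isfinite(z).all()

    def test_unit_count_mismatch_rejected(self):
        r = np.random.default_rng(0).normal(size=(2, 10, 3))
        _, stats = zscore_units(r)
        with pytest.raises(ValueError, match="unit count"):
            zscore_units(np.zeros((2, 10, 5)), stats=stats)

    def test_printed_variant_subtracts_cross_unit_mean(self):
        r = np.random.default_rng(2).normal(10, 2, size=(2, 20, 6))
        z, _ = zscore_units(r, mode="printed")
        # at each time point the (sd-weighted) recombination has zero unit-mean
        _, stats = zscore_units(r, mode="printed")
        back = z * stats["sd"]
        assert np.allclose(back.mean(axis=2), 0.0, atol=1e-10)


class TestWindowing:
    def _series(self, B=2, S=60, U=3):
        offs = np.arange(S) * 10.0 - 300.0
        rng = np.random.default_rng(0)
        return rng.normal(size=(B, S, U)), offs

    def test_center_lag_inverts_windowing(self):
        z, offs = self._series()
        out = offs[20:50]
        wt = window_spikes(z, offs, out)
        X = wt.tensor
        assert np.allclose(X[:, :, :, 20], z[:, 20:50, :])
        assert np.allclose(wt.linear, z[:, 20:50, :].reshape(-1, 3))

    def test_impulse_lands_in_predicted_slots(self):
        z = np.zeros((1, 60, 2))
        z[0, 30, 1] = 1.0
        offs = np.arange(60) * 10.0 - 300.0
        out = offs[20:50]
        X = window_spikes(z, offs, out).tensor
        t_idx, c_idx, l_idx = np.nonzero(X[0])
        assert np.all(c_idx == 1)
        # sample 30 appears at (t, l) pairs with t + l = 30 (series index t+k)
        assert np.all(t_idx + l_idx == 30)
        # (t, l) pairs with t + l = 30 and both in [0, 30): t = 1..29
        assert len(t_idx) == 29

    def test_constant_input_gives_constant_tensor(self):
        z = np.ones((1, 80, 2)) * 3.0
        offs = np.arange(80) * 10.0 - 300.0
        wt = window_spikes(z, offs, offs[20:60])
        assert np.allclose(wt.tensor, 3.0)

    def test_default_geometry_matches_study_shape(self):
        z = np.zeros((2, 209, 73))
        offs = np.arange(209) * 10.0 - 500.0
        out = np.arange(180) * 10.0 - 300.0
        wt = window_spikes(z, offs, out)
        assert wt.tensor.shape == (2, 180, 73, 30)
        assert not wt.padded

    def test_edge_padding_flagged(self):
        z = np.random.default_rng(0).normal(size=(1, 180, 4))
        offs = np.arange(180) * 10.0 - 300.0   # no pre-onset coverage
        out = offs
        wt = window_spikes(z, offs, out)
        assert wt.padded and wt.n_padded == 29
        assert np.allclose(wt.tensor[0, 0, :, :20], 0.0)
        with pytest.raises(ValueError, match="padding is disabled"):
            window_spikes(z, offs, out, allow_padding=False)


def test_zero_phase_filters_preserve_pulse_symmetry():
    # a symmetric rate pulse must stay symmetric through the smoothing chain
    spikes = np.sort(np.concatenate([0.75 + 0.25 * np.linspace(-1, 1, 41) ** 3]))
    rs = compute_firing_rates([spikes], 1500, 300)
    r = rs.rates[0]
    c = int(np.round((750 - rs.offsets_ms[0] - 300) / 10))
    w = 40
    left, right = r[c - w:c], r[c + 1:c + w + 1][::-1]
    skew = np.abs(left - right).max() / max(r.max(), 1e-9)
    assert skew < 1e-6
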