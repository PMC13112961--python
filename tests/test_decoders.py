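"""Decoder contracts: branch non-negativity, subtraction identity, LSTM
recurrence against a hand-rolled reference, parameter accounting, the linear
baseline, co-contraction arithmetic, and weight introspection."""

import numpy as np
import pytest

from sdnet.decoders import (DecoderBlockConfig, DecoderNetwork, build_variant,
                            count_block_parameters, count_parameters,
                            decoder_block_forward, estimate_cocontraction,
                            extract_feature_weights, fit_linear_decoder,
                            predict_linear_decoder, singlenet_forward)

SMALL = DecoderBlockConfig(dropout=0.0)


def random_windowed(rng, B=2, T=8, C=5, L=30):
    return rng.normal(size=(B, T, C, L)).astype(np.float32)


class TestBlockForward:
    def test_rectified_head_nonnegative_over_many_draws(self):
        rng = np.random.default_rng(0)
        mins = []
        for seed in range(40):   # 40 nets x 400 outputs > 1000 draws
            X = random_windowed(rng)
            out = decoder_block_forward(X, SMALL, seed=seed)
            mins.append(out.min())
        assert min(mins) >= 0.0

    def test_zero_weights_give_bias_path(self):
        net = DecoderNetwork("conventional", n_units=4, outputs=("y",),
                             block=SMALL, seed=0)
        state = net.state_dict()
        for k in state:
            if "running" not in k and "gamma" not in k:
                state[k] = np.zeros_like(state[k])
        state["head.bias"] = np.full_like(state["head.bias"], 2.5)
        net.load_state_dict(state)
        X = random_windowed(np.random.default_rng(1), C=4)
        out = net.forward_windowed(X)["net"].data
        # all-zero weights: output is the (normalised) constant bias path
        assert np.allclose(out, out.flat[0])

    def test_feature_dimension_after_pool_and_flatten(self):
        assert DecoderBlockConfig().feature_dim == 112
        assert DecoderBlockConfig().pooled_lags == 7

    def test_series_and_windowed_paths_agree(self):
        rng = np.random.default_rng(2)
        net = DecoderNetwork("single_direction", n_units=6, block=SMALL, seed=3)
        series = rng.normal(size=(2, 40, 6)).astype(np.float32)
        X = np.lib.stride_tricks.sliding_window_view(series, 30, axis=1)
        a = net.forward_series(series)["net"].data
        b = net.forward_windowed(X)["net"].data
        assert np.allclose(a, b, atol=1e-5)

    def test_eval_forward_deterministic(self):
        rng = np.random.default_rng(0)
        net = DecoderNetwork("single_direction", n_units=5, seed=1)
        X = random_windowed(rng)
        a = net.forward_windowed(X)["net"].data
        b = net.forward_windowed(X)["net"].data
        assert np.array_equal(a, b)

    def test_shape_mismatch_names_axes(self):
        net = DecoderNetwork("conventional", n_units=5, seed=0)
        with pytest.raises(ValueError, match="C=5"):
            net.forward_windowed(np.zeros((1, 4, 7, 30), np.float32))


class TestSingleNet:
    def test_subtraction_identity_bit_exact(self):
        rng = np.random.default_rng(4)
        net = DecoderNetwork("single_direction", n_units=5, block=SMALL, seed=5)
        out = singlenet_forward(net, X=random_windowed(rng))
        assert np.array_equal(out["net"], out["ext"] - out["flex"])
        assert out["ext"].min() >= 0 and out["flex"].min() >= 0

    def test_identical_branch_weights_give_zero_net(self):
        net = DecoderNetwork("single_direction", n_units=4, block=SMALL, seed=6)
        state = net.state_dict()
        for k, v in state.items():
            if v.ndim and v.shape[0] == net.n_blocks:
                for r in range(0, v.shape[0], 2):
                    v[r + 1] = v[r]
        net.load_state_dict(state)
        out = singlenet_forward(net, X=random_windowed(np.random.default_rng(7), C=4))
        assert np.allclose(out["net"], 0.0, atol=1e-6)

    def test_net_can_be_negative_though_branches_cannot(self):
        rng = np.random.default_rng(8)
        seen_negative = False
        for seed in range(5):
            net = DecoderNetwork("single_direction", n_units=5, block=SMALL, seed=seed)
            out = singlenet_forward(net, X=random_windowed(rng))
            assert out["ext"].min() >= 0
            seen_negative |= bool((out["net"] < 0).any())
        assert seen_negative


class TestLSTMReference:
    def test_recurrence_matches_hand_rolled_equations(self):
        """sigmoid-gated recurrence: f,i,o gates and tanh cell, step by step."""
        rng = np.random.default_rng(9)
        net = DecoderNetwork("conventional", n_units=3, outputs=("y",),
                             block=DecoderBlockConfig(lstm_hidden=7, dropout=0.0),
                             seed=10)
        R, H = 1, 7
        feat = net.block.feature_dim
        x = rng.normal(size=(R, 2, 6, feat)).astype(np.float32)
        from sdnet.autodiff import Tensor
        ours = net._lstm(Tensor(x)).data

        Wx = net.params["lstm.kernel"].data[0].astype(float)
        Wh = net.params["lstm.recurrent"].data[0].astype(float)
        b = net.params["lstm.bias"].data[0].astype(float)

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        for batch in range(2):
            h = np.zeros(H)
            c = np.zeros(H)
            for t in range(6):
                z = x[0, batch, t] @ Wx + h @ Wh + b
                i, f, g, o = (sig(z[:H]), sig(z[H:2 * H]),
                              np.tanh(z[2 * H:3 * H]), sig(z[3 * H:]))
                c = f * c + i * g
                h = o * np.tanh(c)
                assert np.allclose(ours[0, batch, t], h, atol=1e-6)


class TestVariants:
    def test_labels_and_block_counts(self):
        v = build_variant("single_direction", n_units=5)
        assert v.n_blocks == 8 and v.head_dim == 1 and v.final_activation == "relu"
        v = build_variant("conventional", n_units=5)
        assert v.n_blocks == 1 and v.head_dim == 4 and v.final_activation == "linear"
        v = build_variant("shared", n_units=5)
        assert v.n_blocks == 1 and v.n_heads == 8
        v = build_variant("linear_head", n_units=5)
        assert v.n_blocks == 8 and v.final_activation == "linear"
        with pytest.raises(ValueError, match="unknown architecture"):
            build_variant("transformer", n_units=5)

    def test_linear_head_attains_negative_branch_values(self):
        rng = np.random.default_rng(11)
        net = build_variant("linear_head", n_units=5, block=SMALL, seed=3)
        out = singlenet_forward(net, X=random_windowed(rng))
        assert (out["ext"] < 0).any() or (out["flex"] < 0).any()


class TestParameterCount:
    def test_study_block_core_count(self):
        # closed-form accounting at the study geometry (73 units)
        table = count_block_parameters(DecoderBlockConfig(), n_units=73)
        by = dict(zip(table["layer"], table["parameters"]))
        assert by["conv_temporal"] == 248
        assert by["conv_spatial"] == 1184
        assert by["lstm"] == 8256
        assert by["fc"] == 136
        assert by["head"] == 9
        core = table.loc[table["core"], "parameters"].sum()
        assert core == 9833
        assert round(core / 1000, 1) == 9.8

    def test_conventional_network_rounds_to_9_8k(self):
        net = build_variant("conventional", n_units=73)
        res = count_parameters(net)
        assert round(res["core"] / 1000, 1) == 9.9  # 4-output head adds 27
        res1 = count_parameters(DecoderBlockConfig(), n_units=73, head_dim=1)
        assert res1["core"] == 9833

    def test_count_matches_actual_arrays(self):
        for arch in ("single_direction", "conventional", "shared"):
            net = build_variant(arch, n_units=11)
            res = count_parameters(net)   # asserts accounting == array sizes
            assert res["total"] > res["core"]

    def test_monotone_in_lstm_width(self):
        small = count_parameters(DecoderBlockConfig(lstm_hidden=16))["core"]
        big = count_parameters(DecoderBlockConfig(lstm_hidden=32))["core"]
        assert big > small

    def test_invariant_to_batch_and_sequence(self):
        net = build_variant("conventional", n_units=7, block=SMALL)
        before = count_parameters(net)["total"]
        net.forward_windowed(random_windowed(np.random.default_rng(0), B=3, T=5, C=7))
        assert count_parameters(net)["total"] == before


class TestLinearDecoder:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50, 6))
        beta0 = rng.normal(size=(6, 4))
        beta = fit_linear_decoder(X, X @ beta0)
        assert np.allclose(beta, beta0, atol=1e-9)

    def test_identity_design(self):
        P = np.random.default_rng(0).normal(size=(4, 2))
        assert np.allclose(fit_linear_decoder(np.eye(4), P), P)

    def test_hand_computed_normal_equations(self):
        # X = [[1,0],[1,1],[0,1]], p = [1,2,2]:
        # X'X = [[2,1],[1,2]], X'p = [3,4] -> beta = (1/3)[2,5]
        X = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        p = np.array([[1.0], [2.0], [2.0]])
        beta = fit_linear_decoder(X, p)
        assert np.allclose(beta.ravel(), [2.0 / 3.0, 5.0 / 3.0], atol=1e-12)

    def test_residual_orthogonal_to_column_space(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 5))
        P = rng.normal(size=(40, 3))
        beta = fit_linear_decoder(X, P)
        assert np.max(np.abs(X.T @ (X @ beta - P))) < 1e-8

    def test_rank_deficiency_falls_back_to_pinv(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 4))
        X = np.hstack([X, X[:, :1]])          # duplicated column
        P = rng.normal(size=(30, 2))
        beta = fit_linear_decoder(X, P)
        pinv_beta = np.linalg.pinv(X) @ P
        assert np.allclose(beta, pinv_beta, atol=1e-8)

    def test_predict_shapes_and_zero_cases(self):
        beta = np.zeros((3, 2))
        assert np.allclose(predict_linear_decoder(np.ones((5, 3)), beta), 0.0)
        with pytest.raises(ValueError, match="feature mismatch"):
            predict_linear_decoder(np.ones((5, 4)), beta)


class TestCocontraction:
    def test_worked_arithmetic(self):
        net, co = estimate_cocontraction([2.0, 0.0, 1.0], [1.0, 3.0, 1.0])
        assert np.allclose(net, [1.0, -3.0, 0.0])
        assert np.allclose(co, [1.0, 0.0, 1.0])

    def test_balanced_inputs_peak_at_zero_net(self):
        x = np.array([0.5, 1.0, 0.2])
        net, co = estimate_cocontraction(x, x)
        assert np.allclose(net, 0.0) and np.allclose(co, x)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            estimate_cocontraction([-0.1, 0.2], [0.0, 0.1])

    def test_oracle_directional_torques_recover_commanded_profile(self, tiny_dataset):
        # with ground-truth branches, min(ext, flex) equals the commanded
        # co-contraction exactly, by construction
        ext = tiny_dataset.aux["tau_ext"][..., 0]
        flex = tiny_dataset.aux["tau_flex"][..., 0]
        _, co = estimate_cocontraction(ext, flex)
        assert np.allclose(co, tiny_dataset.aux["coco"], atol=1e-12)


class TestFeatureWeights:
    def test_symmetric_branches_have_identical_profiles(self):
        net = DecoderNetwork("single_direction", n_units=6, block=SMALL, seed=15)
        state = net.state_dict()
        for k, v in state.items():
            if v.ndim and v.shape[0] == net.n_blocks:
                for r in range(0, v.shape[0], 2):
                    v[r + 1] = v[r]
        net.load_state_dict(state)
        sp = extract_feature_weights(net, "spatial")
        for name in net.outputs:
            assert np.allclose(sp[f"{name}_extension"], sp[f"{name}_flexion"])

    def test_temporal_profiles_minmax_normalized(self):
        net = DecoderNetwork("single_direction", n_units=6, seed=16)
        tp = extract_feature_weights(net, "temporal")
        assert tp.values.min() >= 0.0 and tp.values.max() <= 1.0
        assert np.allclose(tp.min(axis=0), 0.0) and np.allclose(tp.max(axis=0), 1.0)
        assert tp.index[0] == -200 and tp.index[-1] == 90

    def test_requires_branched_decoder(self):
        net = build_variant("conventional", n_units=4)
        with pytest.raises(ValueError, match="branched"):
            extract_feature_weights(net, "spatial")
        net2 = build_variant("single_direction", n_units=4)
        with pytest.raises(ValueError, match="unknown mode"):
            extract_feature_weights(net2, "frequency")
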