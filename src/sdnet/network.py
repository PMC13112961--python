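"""The CNN-LSTM decoder block and its branched variants.

A decoder block maps a windowed spike-rate tensor ``[B, T, C, L]`` (trials x
time-steps x units x lag samples) to one output series per time step:

    temporal conv (1 x 30, same padding, 8 filters)
    -> depthwise spatial conv over units (C x 1, depth multiplier 2)
    -> batch norm -> ReLU -> average pool (4) along lags -> flatten (112)
    -> LSTM (16 hidden) -> FC (8, ReLU) -> scalar readout
    -> batch norm -> final activation (ReLU for directional branches).

Architectures:

* ``single_direction`` — one pair of blocks (extension, flexion) per output
  variable; the net output is extension minus flexion.
* ``linear_head``      — same, but the final activation is linear (ablation).
* ``shared``           — one shared CNN+LSTM trunk with per-direction FC/readout
  heads (ablation).
* ``conventional``     — a single block emitting all outputs at once, linear
  final activation (baseline).

Implementation note: the two convolutions compose linearly (batch-norm and the
ReLU come after both, as in the block equations), so the forward pass collapses
the unit axis first and applies the temporal kernel as a banded (Toeplitz)
matrix on sliding windows of the 10-ms rate series.  This avoids materialising
the ~26-fold window redundancy and is exactly equivalent to convolving each
window with 'same' zero padding; ``forward_windowed`` provides the literal
windowed-input path for arbitrary tensors.  All eight branches are evaluated as
one stacked batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["DecoderBlockConfig", "DecoderNetwork", "ARCHITECTURES", "mse_loss"]

ARCHITECTURES = ("single_direction", "conventional", "shared", "linear_head")

DEFAULT_OUTPUTS = ("shoulder_av", "elbow_av", "shoulder_torque", "elbow_torque")


@dataclass(frozen=True)
class DecoderBlockConfig:
    """Architecture hyperparameters of one decoder block."""

    n_temporal_filters: int = 8
    temporal_kernel: int = 30
    depth_multiplier: int = 2
    pool_size: int = 4
    lstm_hidden: int = 16
    fc_units: int = 8
    dropout: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_temporal_filters", "temporal_kernel", "depth_multiplier",
                     "pool_size", "lstm_hidden", "fc_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"DecoderBlockConfig.{name} must be >= 1")

    @property
    def pooled_lags(self) -> int:
        """Lag positions after average pooling (floor semantics)."""
        return self.temporal_kernel // self.pool_size

    @property
    def feature_dim(self) -> int:
        """Flattened feature dimension per time step fed to the LSTM."""
        return self.pooled_lags * self.n_temporal_filters * self.depth_multiplier


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _same_pad_scatter(K: int) -> np.ndarray:
    """Constant 0/1 tensor S with S[j, l, k] = 1 iff k = l + j - pad_left.

    Encodes 'same'-padded cross-correlation of a length-K window with a
    length-K kernel as a banded matrix: Toeplitz[l, k] = W[k - l + pad_left].
    """
    pad_left = (K - 1) // 2
    S = np.zeros((K, K, K), dtype=np.float32)
    j, l = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
    k = l + j - pad_left
    ok = (k >= 0) & (k < K)
    S[j[ok], l[ok], k[ok]] = 1.0
    return S


class DecoderNetwork:
    """Branched CNN-LSTM decoder with stacked-branch numpy evaluation."""

    def __init__(self, architecture: str = "single_direction", n_units: int = 73,
                 outputs: tuple = DEFAULT_OUTPUTS,
                 block: Optional[DecoderBlockConfig] = None, seed: int = 0):
        if architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {architecture!r}; pick one of {ARCHITECTURES}")
        self.architecture = architecture
        self.n_units = int(n_units)
        self.outputs = tuple(outputs)
        self.block = block or DecoderBlockConfig()
        V = len(self.outputs)
        if architecture == "conventional":
            self.n_blocks, self.n_heads, self.head_dim = 1, 1, V
            self.final_activation = "linear"
        elif architecture == "shared":
            self.n_blocks, self.n_heads, self.head_dim = 1, 2 * V, 1
            self.final_activation = "relu"
        else:
            self.n_blocks = self.n_heads = 2 * V
            self.head_dim = 1
            self.final_activation = "relu" if architecture == "single_direction" else "linear"
        self._scatter = _same_pad_scatter(self.block.temporal_kernel)
        # fine-tuning mode: every batch norm normalises with its (frozen)
        # running statistics even during training forward passes — small
        # fine-tune batches give statistics estimates too noisy to adapt on
        self.inference_bn = False
        self._init_parameters(np.random.default_rng(seed))

    # ------------------------------------------------------------------ setup
    def _init_parameters(self, rng: np.random.Generator) -> None:
        b, C = self.block, self.n_units
        R, Q = self.n_blocks, self.n_heads
        F, D, K = b.n_temporal_filters, b.depth_multiplier, b.temporal_kernel
        H, U, O = b.lstm_hidden, b.fc_units, self.head_dim
        feat = b.feature_dim
        p: dict[str, Tensor] = {}
        p["conv_temporal.kernel"] = Tensor(_glorot(rng, (R, F, K), K, F), True, name="conv_temporal.kernel")
        p["conv_temporal.bias"] = Tensor(np.zeros((R, F), np.float32), True)
        p["conv_spatial.kernel"] = Tensor(_glorot(rng, (R, C, F, D), C, D), True)
        p["conv_spatial.bias"] = Tensor(np.zeros((R, F * D), np.float32), True)
        p["bn_conv.gamma"] = Tensor(np.ones((R, 1, 1, 1, F, D), np.float32), True)
        p["bn_conv.beta"] = Tensor(np.zeros((R, 1, 1, 1, F, D), np.float32), True)
        p["lstm.kernel"] = Tensor(_glorot(rng, (R, feat, 4 * H), feat, 4 * H), True)
        p["lstm.recurrent"] = Tensor(_glorot(rng, (R, H, 4 * H), H, 4 * H), True)
        lstm_bias = np.zeros((R, 4 * H), np.float32)
        lstm_bias[:, H:2 * H] = 1.0  # forget-gate bias
        p["lstm.bias"] = Tensor(lstm_bias, True)
        p["fc.kernel"] = Tensor(_glorot(rng, (Q, H, U), H, U), True)
        p["fc.bias"] = Tensor(np.zeros((Q, U), np.float32), True)
        p["head.kernel"] = Tensor(_glorot(rng, (Q, U, O), U, O), True)
        p["head.bias"] = Tensor(np.zeros((Q, O), np.float32), True)
        p["bn_out.gamma"] = Tensor(np.ones((Q, 1, 1, O), np.float32), True)
        p["bn_out.beta"] = Tensor(np.zeros((Q, 1, 1, O), np.float32), True)
        self.params = p
        self.running = {
            "bn_conv": {"mean": np.zeros((R, 1, 1, 1, F, D), np.float32),
                        "var": np.ones((R, 1, 1, 1, F, D), np.float32)},
            "bn_out": {"mean": np.zeros((Q, 1, 1, O), np.float32),
                       "var": np.ones((Q, 1, 1, O), np.float32)},
        }

    CONV_PARAMS = ("conv_temporal.kernel", "conv_temporal.bias",
                   "conv_spatial.kernel", "conv_spatial.bias",
                   "bn_conv.gamma", "bn_conv.beta")

    def trainable_names(self, finetune: bool = False) -> list[str]:
        """Parameter names updated by the optimizer.

        Under fine-tuning the convolutional feature extractor (both conv
        kernels, their biases and the conv batch norm) is frozen; only the
        LSTM, FC and readout layers adapt.
        """
        if not finetune:
            return list(self.params)
        return [k for k in self.params if k not in self.CONV_PARAMS]

    # -------------------------------------------------------------- forward
    def _toeplitz(self) -> Tensor:
        return ad.einsum2("rfj,jlk->rflk", self.params["conv_temporal.kernel"],
                          Tensor(self._scatter))

    def _conv_bias(self) -> Tensor:
        """Composite bias after both convolutions, shape [R, 1, 1, 1, F, D]."""
        R = self.n_blocks
        F, D = self.block.n_temporal_filters, self.block.depth_multiplier
        wsum = ad.reduce_sum(self.params["conv_spatial.kernel"], axis=1)      # [R,F,D]
        bt = ad.reshape(self.params["conv_temporal.bias"], (R, F, 1))
        term = ad.mul(bt, wsum)
        beff = ad.add(term, ad.reshape(self.params["conv_spatial.bias"], (R, F, D)))
        return ad.reshape(beff, (R, 1, 1, 1, F, D))

    def _tail(self, y: Tensor, training: bool, rng) -> Tensor:
        """Shared pipeline from the composed-conv output [R,B,T,L,F,D] onward."""
        b = self.block
        R = self.n_blocks
        B, T = y.shape[1], y.shape[2]
        y = ad.add_(y, self._conv_bias())   # in-place: y is a fresh einsum output
        y = ad.batch_norm_relu(y, self.params["bn_conv.gamma"], self.params["bn_conv.beta"],
                               axes=(1, 2, 3), running=self.running["bn_conv"],
                               training=training and not self.inference_bn)
        G = b.pooled_lags
        y = ad.narrow(y, 3, 0, G * b.pool_size)
        y = ad.reshape(y, (R, B, T, G, b.pool_size, b.n_temporal_filters, b.depth_multiplier))
        y = ad.reduce_mean(y, axis=4)
        feats = ad.reshape(y, (R, B, T, b.feature_dim))
        H = self._lstm(feats)
        if self.architecture == "shared":
            H = ad.reshape(H, (B, T, b.lstm_hidden))
            z = ad.einsum2("bth,rhu->rbtu", H, self.params["fc.kernel"])
        else:
            z = ad.einsum2("rbth,rhu->rbtu", H, self.params["fc.kernel"])
        Q = self.n_heads
        z = ad.add(z, ad.reshape(self.params["fc.bias"], (Q, 1, 1, b.fc_units)))
        z = ad.relu(z)
        if training and b.dropout > 0:
            if rng is None:
                raise ValueError("training-mode forward requires an rng for dropout")
            keep = 1.0 - b.dropout
            mask = (rng.random(z.shape) < keep).astype(np.float32) / keep
            z = ad.mul(z, Tensor(mask))
        z = ad.einsum2("rbtu,ruo->rbto", z, self.params["head.kernel"])
        z = ad.add(z, ad.reshape(self.params["head.bias"], (Q, 1, 1, self.head_dim)))
        z = ad.batch_norm(z, self.params["bn_out.gamma"], self.params["bn_out.beta"],
                          axes=(1, 2), running=self.running["bn_out"],
                          training=training and not self.inference_bn)
        if self.final_activation == "relu":
            z = ad.relu(z)
        return z

    def _lstm(self, feats: Tensor) -> Tensor:
        """Stacked-branch LSTM over the time axis: feats [R,B,T,feat] -> [R,B,T,H]."""
        R, B, T, _ = feats.shape
        Hn = self.block.lstm_hidden
        Wx, Wh = self.params["lstm.kernel"], self.params["lstm.recurrent"]
        bias = ad.reshape(self.params["lstm.bias"], (R, 1, 4 * Hn))
        # input projection for all steps at once; the loop only carries recurrence
        xz_all = ad.einsum2("rbtm,rmh->rbth", feats, Wx)
        h = Tensor(np.zeros((R, B, Hn), np.float32))
        c = Tensor(np.zeros((R, B, Hn), np.float32))
        hs = []
        for t in range(T):
            x_t = ad.reshape(ad.narrow(xz_all, 2, t, 1), (R, B, 4 * Hn))
            z = ad.add(ad.add(x_t, ad.matmul(h, Wh)), bias)
            i = ad.sigmoid(ad.narrow(z, -1, 0, Hn))
            f = ad.sigmoid(ad.narrow(z, -1, Hn, Hn))
            g = ad.tanh(ad.narrow(z, -1, 2 * Hn, Hn))
            o = ad.sigmoid(ad.narrow(z, -1, 3 * Hn, Hn))
            c = ad.add(ad.mul(f, c), ad.mul(i, g))
            h = ad.mul(o, ad.tanh(c))
            hs.append(h)
        return ad.stack_last(hs, axis=2)

    def _collect(self, z: Tensor) -> dict:
        """Assemble net/extension/flexion outputs from head activations."""
        B, T = z.shape[1], z.shape[2]
        V = len(self.outputs)
        if self.architecture == "conventional":   # single block: [1,B,T,V]
            net = ad.reshape(z, (B, T, V))
            return {"net": net, "ext": None, "flex": None}
        pairs = ad.reshape(z, (V, 2, B, T))
        ext = ad.reshape(ad.narrow(pairs, 1, 0, 1), (V, B, T))
        flex = ad.reshape(ad.narrow(pairs, 1, 1, 1), (V, B, T))
        net = ad.sub(ext, flex)
        return {"net": ad.transpose(net, (1, 2, 0)),
                "ext": ad.transpose(ext, (1, 2, 0)),
                "flex": ad.transpose(flex, (1, 2, 0))}

    def forward_series(self, series: np.ndarray, training: bool = False,
                       rng: Optional[np.random.Generator] = None) -> dict:
        """Forward pass from a padded standardized rate series.

        ``series`` has shape ``[B, S, C]`` with ``S = T + K - 1``: sample ``s``
        is the rate at lag offset ``s`` of output step ``t = s - k`` — i.e. the
        windowed tensor satisfies ``X[b, t, c, k] = series[b, t + k, c]``.
        Returns dict of Tensors ``net`` [B,T,V] and, for branched
        architectures, ``ext``/``flex`` [B,T,V].
        """
        series = np.ascontiguousarray(series, dtype=np.float32)
        K = self.block.temporal_kernel
        if series.shape[1] < K:
            raise ValueError(f"series axis 1 must cover at least {K} samples")
        P = Tensor(series)
        Z = ad.einsum2("bsc,rcfd->rbsfd", P, self.params["conv_spatial.kernel"])
        Zw = ad.sliding_windows(Z, axis=2, length=K)           # [R,B,T,K,F,D]
        y = ad.einsum2("rbtkfd,rflk->rbtlfd", Zw, self._toeplitz())
        return self._collect(self._tail(y, training, rng))

    def forward_windowed(self, X: np.ndarray, training: bool = False,
                         rng: Optional[np.random.Generator] = None) -> dict:
        """Forward pass from an explicit windowed tensor ``[B, T, C, L]``.

        Mathematically identical to :meth:`forward_series` when the tensor was
        produced by sliding-window extraction; also valid for arbitrary
        tensors (used by contract tests).
        """
        X = np.ascontiguousarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[2] != self.n_units or X.shape[3] != self.block.temporal_kernel:
            raise ValueError(
                f"expected [B, T, C={self.n_units}, L={self.block.temporal_kernel}] input, "
                f"got {X.shape}")
        Zw = ad.einsum2("btck,rcfd->rbtkfd", Tensor(X), self.params["conv_spatial.kernel"])
        y = ad.einsum2("rbtkfd,rflk->rbtlfd", Zw, self._toeplitz())
        return self._collect(self._tail(y, training, rng))

    # ------------------------------------------------------------- weights io
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.params.items()}
        for bn, stats in self.running.items():
            state[f"{bn}.running_mean"] = stats["mean"].copy()
            state[f"{bn}.running_var"] = stats["var"].copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {v.data.shape}")
            v.data = arr.copy()
        for bn, stats in self.running.items():
            stats["mean"] = np.asarray(state[f"{bn}.running_mean"], np.float32).copy()
            stats["var"] = np.asarray(state[f"{bn}.running_var"], np.float32).copy()

    def config_dict(self) -> dict:
        return {"architecture": self.architecture, "n_units": self.n_units,
                "outputs": list(self.outputs), "block": asdict(self.block)}

    @classmethod
    def from_config(cls, cfg: dict, seed: int = 0) -> "DecoderNetwork":
        return cls(cfg["architecture"], cfg["n_units"], tuple(cfg["outputs"]),
                   DecoderBlockConfig(**cfg["block"]), seed=seed)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    diff = ad.sub(pred, Tensor(np.asarray(target, dtype=np.float32)))
    return ad.reduce_mean(ad.square(diff))
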