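"""Decoder variants, parameter accounting, the linear baseline, co-contraction.

The single-direction decoder estimates each joint variable with a pair of
rectified CNN-LSTM branches (extension, flexion) and reports their difference
as the net variable; because both branch outputs are non-negative, the
simultaneous activation of antagonist drives is observable as

    tau_co = min(tau_extension, tau_flexion),
    tau_net = tau_extension - tau_flexion,

which peaks when the net torque crosses zero.  The conventional baseline is a
single block predicting all outputs at once; the linear baseline is ordinary
least squares on the window-centre population vector.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .network import ARCHITECTURES, DecoderBlockConfig, DecoderNetwork, DEFAULT_OUTPUTS

__all__ = ["DecoderBlockConfig", "DecoderNetwork", "build_variant",
           "count_parameters", "count_block_parameters", "decoder_block_forward",
           "singlenet_forward", "fit_linear_decoder", "predict_linear_decoder",
           "estimate_cocontraction", "extract_feature_weights"]

logger = logging.getLogger(__name__)


def build_variant(architecture: str, n_units: int = 73,
                  outputs: tuple = DEFAULT_OUTPUTS,
                  block: Optional[DecoderBlockConfig] = None,
                  seed: int = 0) -> DecoderNetwork:
    """Instantiate an architecture variant by label.

    ``single_direction`` (rectified branch pairs), ``conventional`` (one block,
    all outputs, linear), ``shared`` (shared CNN+LSTM trunk, per-direction
    heads) or ``linear_head`` (branch pairs without the rectifying constraint).
    """
    return DecoderNetwork(architecture, n_units, outputs, block, seed)


def count_block_parameters(block: DecoderBlockConfig = DecoderBlockConfig(),
                           n_units: int = 73, head_dim: int = 1) -> pd.DataFrame:
    """Closed-form per-layer parameter table for a single decoder block.

    The ``core`` flag excludes normalisation layers, matching the convention
    of reporting convolution/LSTM/FC/readout weights only.
    """
    F, K = block.n_temporal_filters, block.temporal_kernel
    D, H, U = block.depth_multiplier, block.lstm_hidden, block.fc_units
    feat = block.feature_dim
    rows = [
        ("conv_temporal", F * K + F, True),
        ("conv_spatial", n_units * F * D + F * D, True),
        ("bn_conv", 2 * F * D, False),
        ("lstm", 4 * H * (feat + H + 1), True),
        ("fc", H * U + U, True),
        ("head", U * head_dim + head_dim, True),
        ("bn_out", 2 * head_dim, False),
    ]
    return pd.DataFrame(rows, columns=["layer", "parameters", "core"])


def count_parameters(decoder: Union[DecoderNetwork, DecoderBlockConfig],
                     n_units: int = 73, head_dim: int = 1) -> dict:
    """Trainable-parameter accounting for a block config or a whole network.

    Returns ``{"core": ..., "total": ..., "table": per-layer DataFrame}``;
    ``core`` excludes batch-norm parameters, ``total`` includes them.
    """
    if isinstance(decoder, DecoderBlockConfig):
        table = count_block_parameters(decoder, n_units, head_dim)
    else:
        net = decoder
        blk = count_block_parameters(net.block, net.n_units, net.head_dim)
        reps = {"conv_temporal": net.n_blocks, "conv_spatial": net.n_blocks,
                "bn_conv": net.n_blocks, "lstm": net.n_blocks,
                "fc": net.n_heads, "head": net.n_heads, "bn_out": net.n_heads}
        table = blk.assign(parameters=[int(r.parameters * reps[r.layer])
                                       for r in blk.itertuples()])
        actual = sum(int(np.prod(p.data.shape)) for p in net.params.values())
        assert actual == int(table["parameters"].sum()), "accounting drift"
    core = int(table.loc[table["core"], "parameters"].sum())
    total = int(table["parameters"].sum())
    return {"core": core, "total": total, "table": table}


def decoder_block_forward(X: np.ndarray, block: Optional[DecoderBlockConfig] = None,
                          network: Optional[DecoderNetwork] = None,
                          seed: int = 0) -> np.ndarray:
    """Evaluate a single decoder block on a windowed tensor ``[B, T, C, L]``.

    Supply a one-block ``network`` to reuse weights; otherwise a fresh
    rectified-head block is initialised from ``seed``.  Returns the per-step
    output series ``[B, T]``.
    """
    if network is None:
        network = DecoderNetwork("conventional", n_units=X.shape[2],
                                 outputs=("y",), block=block, seed=seed)
        network.final_activation = "relu"
    if network.n_blocks != 1 or network.head_dim != 1:
        raise ValueError("decoder_block_forward expects a single scalar-output block")
    out = network.forward_windowed(X)
    return out["net"].data[..., 0]


def singlenet_forward(network: DecoderNetwork,
                      X: Optional[np.ndarray] = None,
                      series: Optional[np.ndarray] = None) -> dict:
    """Evaluation-mode forward pass of a branched decoder.

    Returns numpy arrays ``net``, ``ext``, ``flex`` of shape ``[B, T, V]``
    with ``net = ext - flex`` exactly and both branch series non-negative
    under rectified heads.
    """
    if network.head_dim != 1:
        raise ValueError("singlenet_forward requires a branched architecture")
    if (X is None) == (series is None):
        raise ValueError("supply exactly one of X (windowed) or series")
    out = (network.forward_windowed(X) if X is not None
           else network.forward_series(series))
    return {k: (v.data if v is not None else None) for k, v in out.items()}


def fit_linear_decoder(X: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Least-squares readout ``beta`` for the linear baseline ``P = X beta``.

    Uses the exact normal-equation solution when ``X`` has full column rank,
    falling back to the minimum-norm pseudo-inverse solution otherwise (the
    rank deficiency is logged, not raised).
    """
    X = np.asarray(X, dtype=float)
    P = np.asarray(P, dtype=float)
    if X.shape[0] != P.shape[0]:
        raise ValueError(f"row mismatch: X has {X.shape[0]}, P has {P.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return np.linalg.solve(X.T @ X, X.T @ P)
    logger.warning("design matrix rank %d < %d columns; using pseudo-inverse",
                   rank, X.shape[1])
    return np.linalg.pinv(X) @ P


def predict_linear_decoder(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"feature mismatch: X has {X.shape[1]}, beta {beta.shape[0]}")
    return X @ beta


def estimate_cocontraction(extension: np.ndarray, flexion: np.ndarray,
                           atol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Net and co-contraction series from non-negative directional estimates.

    ``net = ext - flex``; ``co = min(ext, flex)`` — non-negative, zero wherever
    either input is zero, and maximal where the directional estimates balance.
    """
    ext = np.asarray(extension, dtype=float)
    flex = np.asarray(flexion, dtype=float)
    if np.any(ext < -atol) or np.any(flex < -atol):
        raise ValueError("directional series must be non-negative")
    ext = np.maximum(ext, 0.0)
    flex = np.maximum(flex, 0.0)
    return ext - flex, np.minimum(ext, flex)


def extract_feature_weights(network: DecoderNetwork, mode: str = "spatial") -> pd.DataFrame:
    """Learned spatial or temporal weight profiles per branch.

    ``spatial``: per-unit L2 norm of the depthwise spatial kernels (which
    units each branch attends to).  ``temporal``: per-lag L2 norm of the
    temporal kernels, min-max normalised to [0, 1] within each branch (which
    lead/lag times drive the branch).  Requires a branched architecture so
    extension and flexion profiles can be contrasted.
    """
    if network.head_dim != 1 or network.n_blocks < 2:
        raise ValueError("feature-weight extraction requires a branched (single-direction) decoder")
    branches = [f"{name}_{direction}" for name in network.outputs
                for direction in ("extension", "flexion")]
    if mode == "spatial":
        Wd = network.params["conv_spatial.kernel"].data      # [R, C, F, D]
        prof = np.sqrt((Wd.astype(float) ** 2).sum(axis=(2, 3)))
        return pd.DataFrame(prof.T, columns=branches,
                            index=pd.RangeIndex(network.n_units, name="unit"))
    if mode == "temporal":
        Wt = network.params["conv_temporal.kernel"].data     # [R, F, K]
        prof = np.sqrt((Wt.astype(float) ** 2).sum(axis=1))  # [R, K]
        lo = prof.min(axis=1, keepdims=True)
        rng = np.ptp(prof, axis=1, keepdims=True)
        prof = (prof - lo) / np.where(rng > 0, rng, 1.0)
        lags_ms = (np.arange(network.block.temporal_kernel) - 20) * 10
        return pd.DataFrame(prof.T, columns=branches,
                            index=pd.Index(lags_ms, name="lag_ms"))
    raise ValueError(f"unknown mode {mode!r}; use 'spatial' or 'temporal'")
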