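"""Shared test utilities."""

import numpy as np

from sdnet.datasets import DecodingDataset, OUTPUT_NAMES


def mini_dataset(B=24, T=12, U=4, n_targets=2, seed=0):
    """A small decodable dataset: labels are mixtures of the window-centre rates."""
    rng = np.random.default_rng(seed)
    S = T + 29
    rates = rng.gamma(2.0, 5.0, size=(B, S, U))
    W = rng.normal(size=(U, 4))
    labels = np.einsum("bsu,uv->bsv", rates, W)[:, 20:20 + T, :] * 0.01
    groups = np.repeat(np.arange(B // n_targets // 2), 2 * n_targets)[:B]
    targets = np.tile(np.arange(n_targets), B // n_targets)
    aux = {"theta": np.zeros((B, T, 2)), "hand": np.zeros((B, T, 2))}
    return DecodingDataset(rates, np.arange(S) * 10.0 - 500.0, labels,
                           np.arange(T) * 10.0 - 300.0, targets, groups,
                           OUTPUT_NAMES, aux, [], {}, {"mini": True})
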