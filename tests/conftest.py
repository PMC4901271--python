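"""Shared fixtures and independent oracles.

The oracles deliberately avoid the code paths they check: rank
correlation is computed from explicitly constructed average ranks and
``np.corrcoef``; RDMs are built pair by pair in a plain loop.
"""

from __future__ import annotations

import numpy as np
import pytest


def rank_with_average_ties(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) built explicitly from sorted positions."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        # positions i..j (0-based) share the value; average their 1-based ranks
        avg = (i + j) / 2.0 + 1.0
        for p in range(i, j + 1):
            ranks[order[p]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman R as Pearson correlation of explicit average ranks."""
    rx = rank_with_average_ties(x)
    ry = rank_with_average_ties(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def correlation_rdm_oracle(patterns: np.ndarray) -> np.ndarray:
    """Condensed 1 - Spearman RDM built pair by pair."""
    n = patterns.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(1.0 - spearman_oracle(patterns[i], patterns[j]))
    return np.asarray(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gt():
    """Small deterministic ground truth usable across modules."""
    from neurorsa.synth import make_ground_truth

    return make_ground_truth(
        n_conditions=8, n_layers=3, latent_dim=10, seed=7,
        base_latency_ms=100.0, latency_step_ms=20.0,
        epoch_ms=np.arange(0.0, 241.0, 20.0))
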