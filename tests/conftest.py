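"""Shared fixtures.

The expensive fixture is ``benchmark_grid``: the full 12-method suite on
the synthetic effect-size grid (delta in {0, 0.2, 0.5, 0.8}, 10 seeds at
n=1000, d=128, k=10).  It is computed once per session and shared by all
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from shortcut_audit import (
    EmbeddingDataset,
    SyntheticConfig,
    generate_synthetic,
    run_suite,
)

GRID_DELTAS = (0.0, 0.2, 0.5, 0.8)
GRID_SEEDS = 10
GRID_N, GRID_D, GRID_K = 1000, 128, 10


@pytest.fixture(scope="session")
def benchmark_grid():
    """{(delta, seed): (results dict, true_dims frozenset)} for the full suite."""
    out = {}
    for delta in GRID_DELTAS:
        for seed in range(GRID_SEEDS):
            syn = generate_synthetic(
                SyntheticConfig(
                    n=GRID_N, d=GRID_D, delta=delta, k=GRID_K, seed=seed
                )
            )
            out[(delta, seed)] = (run_suite(syn), syn.true_dims)
    return out


def make_dataset(
    n=200,
    d=8,
    seed=0,
    attr_shift=0.0,
    shift_dims=(),
    label_rate=0.5,
    y_from_dim=None,
):
    """Small hand-rolled dataset for unit tests: standard-normal embeddings
    with an optional attribute mean shift and an optional Y encoded in one
    dimension."""
    rng = np.random.default_rng(seed)
    a = (rng.random(n) >= 0.5).astype(np.int64)
    E = rng.standard_normal((n, d))
    for j in shift_dims:
        E[:, j] += np.where(a == 1, attr_shift / 2, -attr_shift / 2)
    if y_from_dim is None:
        y = (rng.random(n) < label_rate).astype(np.int64)
    else:
        y = (E[:, y_from_dim] > 0).astype(np.int64)
    return EmbeddingDataset(
        embeddings=E, task_labels=y, attributes={"group": a}
    )


@pytest.fixture
def small_shortcut_dataset():
    return make_dataset(n=300, d=10, seed=3, attr_shift=2.0, shift_dims=(1, 4))


@pytest.fixture
def null_dataset():
    return make_dataset(n=300, d=10, seed=4)
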