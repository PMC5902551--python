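import numpy as np
import pytest

from editnet import (
    MotifModel,
    SimulationConfig,
    SingleCellModuleSpec,
    TrainingConfig,
    generate_dataset,
    train_single_cell_module,
)

# Desk-scale study conditions shared across tests: 25-base flanks (51-bp
# windows), full-strength neighbour motif, balanced classes.
DESK_FLANK = 25
DESK_MOTIF = MotifModel(decay_halfwidth=25, signal_strength=0.9)


def desk_config(n_per_class: int, seed: int, flank: int = DESK_FLANK) -> SimulationConfig:
    # genome sized for ~40% window occupancy so rejection sampling stays fast
    per_contig = max(2 * flank + 1, int(3 * n_per_class * 3 * (2 * flank + 1) / 2))
    return SimulationConfig(
        genome_length=per_contig,
        n_contigs=2,
        n_positives=n_per_class,
        n_snps=n_per_class,
        n_others=n_per_class,
        flank=flank,
        master_seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """260 candidates per class on a fresh genome; reused read-only."""
    return generate_dataset(desk_config(260, seed=11), DESK_MOTIF)


@pytest.fixture(scope="session")
def split_arrays(small_dataset):
    """(X_train, y_train, X_test, y_test) with a class-stratified 180/80 split."""
    X, y = small_dataset.training_arrays()
    rng = np.random.default_rng(7)
    train_idx, test_idx = [], []
    for label in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == label))
        train_idx.extend(idx[:180])
        test_idx.extend(idx[180:])
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    return X[train_idx], y[train_idx], X[test_idx], y[test_idx]


@pytest.fixture(scope="session")
def trained_module(split_arrays):
    """A reduced two-scale module trained once and shared read-only."""
    X, y, _, _ = split_arrays
    spec = SingleCellModuleSpec(scales=(25, 10), n_members=2, hidden_sizes=(24,))
    config = TrainingConfig(epochs=12)
    return train_single_cell_module(X, y, spec, config, seed=5)
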