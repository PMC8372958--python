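import numpy as np
import pandas as pd
import pytest

import cytogate as cg
from cytogate.simulate import (
    default_background_components,
    default_cell_components,
    default_fluor_model,
    write_batch,
)


@pytest.fixture(scope="session")
def quick_config():
    """Small-but-deterministic fit configuration for module tests."""
    return cg.FitConfig(n_random_inits=2, n_memory_inits=2, seed=12345)


@pytest.fixture(scope="session")
def small_batch_dir(tmp_path_factory):
    """Desk-scale synthetic batch: blank + 2 cell samples + beads."""
    d = tmp_path_factory.mktemp("batch") / "experiment"
    write_batch(
        d,
        seed=42,
        n_samples=2,
        events_per_sample=5000,
        blank_events=8000,
        bead_events=6000,
    )
    return d


def load_truth(batch_dir, stem):
    return pd.read_csv(batch_dir / "truth" / f"{stem}.truth.csv")


@pytest.fixture(scope="session")
def cell_sample():
    """One cell sample with 20% doublets and no background events."""
    table, truth = cg.simulate_cells(
        12_000,
        default_cell_components(),
        default_background_components(),
        background_fraction=0.0,
        doublet_fraction=0.2,
        fluor_model=default_fluor_model(),
        seed=7,
    )
    return table, truth


def match_accuracy(assignments, truth_labels, k):
    """Best-permutation agreement between cluster assignments and truth."""
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((k, k))
    for a, b in zip(assignments, truth_labels):
        if 0 <= a < k and 0 <= b < k:
            conf[a, b] += 1
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / len(truth_labels)
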