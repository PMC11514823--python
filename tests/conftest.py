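import warnings

import pytest

from meripvar.pipeline import call_and_quantify
from meripvar.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic experiment shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(SimulationConfig(), seed=0)


@pytest.fixture(scope="session")
def default_state(default_dataset):
    """Peaks + raw and normalized ratio matrices for the default dataset."""
    return call_and_quantify(default_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast dataset for I/O and structural tests."""
    cfg = SimulationConfig(n_genes=40, n_constitutive=10, n_variable=8, depth=150.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(cfg, seed=3)


def peak_lookup(state):
    """(gene_id, window_index) -> peak_id over all emitted peaks."""
    out = {}
    for pk in state.peaks:
        for w in pk.window_indices:
            out[(pk.gene_id, w)] = pk.peak_id
    return out
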