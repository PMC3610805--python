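import numpy as np
import pytest

from cisxpred import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-population panel with planted linear effects."""
    spec = SimulationSpec(
        n_per_pop=30,
        n_populations=2,
        n_genes=4,
        snps_per_gene=15,
        h2=0.5,
        n_causal=2,
        n_features=5,
        seed=7,
    )
    ds, truth = simulate_dataset(spec)
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
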