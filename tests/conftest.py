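import numpy as np
import pytest

import dosagescan as ds


@pytest.fixture(scope="session")
def small_scenario():
    """A small simulated genome shared by read-only tests: 1,500 genes with
    a decaying duplicate spectrum, counts at roughly 10-35x expected count
    per single-copy gene."""
    cfg = ds.simulate.SimulationConfig(n_genes=1500, seed=101)
    genes, truth = ds.simulate.simulate_reference(cfg)
    counts = ds.simulate.simulate_counts(
        genes, truth, cfg.library_size, cfg.gc_intercept, cfg.gc_slope,
        seed=102)
    return cfg, genes, truth, counts


@pytest.fixture(scope="session")
def small_ensemble(small_scenario):
    cfg, genes, truth, counts = small_scenario
    return ds.fit_gc_ensemble(genes, counts, n_repeats=25, seed=103)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
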