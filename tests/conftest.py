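import numpy as np
import pytest

from orthointron import SynthConfig, generate_species_pair


@pytest.fixture(scope="session")
def small_pair():
    """A 150-gene synthetic two-species set shared across tests."""
    cfg = SynthConfig(seed=42, n_genes=150)
    ds_m, ds_z, truth = generate_species_pair(cfg)
    return cfg, ds_m, ds_z, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
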