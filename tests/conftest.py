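import numpy as np
import pytest

from polycap.synthetic_data import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=11,
        accessions=(("hexa", 6), ("octo", 8)),
        n_loci=200,
        mean_depth=80.0,
        n_genes=300,
        probe_count=5,
    )
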