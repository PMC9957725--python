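import numpy as np
import pytest

from utrland.synthetic_data import SimulationConfig, make_genome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=42,
        depth=20_000,
        replicates=1,
        n_genes_per_class={
            "sharp_top": 4,
            "broad_mixed": 3,
            "sharp_nontop": 4,
            "prte_plus": 3,
        },
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_genome(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
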