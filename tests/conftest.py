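import numpy as np
import pytest

from diurnalqpcr import SimulationDesign, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Default-design synthetic dataset, shared across read-only tests."""
    design = SimulationDesign(seed=11)
    return generate_dataset(design)


@pytest.fixture(scope="session")
def clean_dataset():
    """No missing data, modest noise: convenient for exact invariants."""
    design = SimulationDesign(
        n_genes=40, noise_sd=0.3, failure_rate=0.0, column_shift_sd=0.3, seed=7
    )
    return generate_dataset(design)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
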