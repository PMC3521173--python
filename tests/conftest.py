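import numpy as np
import pytest

from enhscan import SimulationConfig, simulate_dataset

ALL_TISSUES = ("FB", "MB", "LB", "HT")


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        seed=11,
        n_genes=40,
        n_enhancers_per_tissue={t: 20 for t in ALL_TISSUES},
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def dataset():
    """One medium synthetic dataset shared by read-only tests."""
    config = small_config()
    annotation, alignments, truth = simulate_dataset(config)
    return config, annotation, alignments, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
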