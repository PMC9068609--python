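import numpy as np
import pytest

from plankmap.core_data import AsvTable
from plankmap.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced survey: 10 stations, 5 years, 2 groups, cheap to simulate."""
    return SimConfig(
        n_stations=10,
        n_years=5,
        groups=("cyanobacteria", "photosynthetic_protists"),
        n_asvs_per_group=15,
        depth_median_reads=25_000.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One realization of the full default synthetic world."""
    return simulate_dataset(SimConfig(), seed=2024)


@pytest.fixture
def toy_table() -> AsvTable:
    counts = np.array([[3, 0],
                       [2, 4],
                       [1, 5]])
    return AsvTable(["a1", "a2", "a3"], ["s1", "s2"], counts)
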