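import numpy as np
import pytest

from limnodiv.core import CommunityMatrix, LifeFormCatalogue
from limnodiv.simulate import SimulationConfig, simulate_lakes


@pytest.fixture(scope="session")
def tiny_community() -> CommunityMatrix:
    """3 sites x 4 species worked example: richness (2, 2, 1)."""
    return CommunityMatrix(
        ("s1", "s2", "s3"),
        ("spA", "spB", "spC", "spD"),
        np.array([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 0, 1]]),
    )


@pytest.fixture(scope="session")
def filtered_dataset():
    """One default filtered-mode synthetic dataset (study-scale shapes)."""
    return simulate_lakes(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def neutral_dataset():
    return simulate_lakes(SimulationConfig(seed=101, assembly="neutral"))


@pytest.fixture(scope="session")
def synthetic_catalogue(filtered_dataset) -> LifeFormCatalogue:
    return LifeFormCatalogue(filtered_dataset.catalogue.assign(growth_form=""))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
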