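import numpy as np
import pytest

from nemapatch import SimulationConfig, SpeciesParams, datasets


@pytest.fixture(scope="session")
def bci_records():
    return datasets.bci_collection_records()


@pytest.fixture(scope="session")
def gustavia_records():
    return datasets.gustavia_collection_records()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def homogeneous_config():
    """Single homogeneous species over a large patch grid (σ = 0)."""
    return SimulationConfig(
        seed=5,
        sites_per_locality=50,
        quadrats_per_site=10,
        patches_per_quadrat=20,
        species={"C. briggsae": SpeciesParams(lam=1.08, sigma=0.0)},
    )
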