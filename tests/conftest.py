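import numpy as np
import pytest
from hypothesis import settings

# reproducible property tests: derive examples deterministically
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mitocomp import load_fixture
from mitocomp.simulate import SyntheticSpec, generate_mitogenome


@pytest.fixture(scope="session")
def macro_ann():
    return load_fixture("macrodactylus")


@pytest.fixture(scope="session")
def tenui_ann():
    return load_fixture("tenuidactylus")


@pytest.fixture(scope="session")
def ancestral():
    return load_fixture("ancestral_pancrustacean")


@pytest.fixture(scope="session")
def synthetic_genome():
    """One deterministic synthetic mitogenome shared across tests."""
    return generate_mitogenome(SyntheticSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
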