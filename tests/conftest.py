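import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    from deff import fixture_library

    return fixture_library()


@pytest.fixture(scope="session")
def ethanol():
    from deff import MolecularGraph

    return MolecularGraph.from_smiles("CCO")


@pytest.fixture(scope="session")
def small_water_box(library):
    from deff import make_water_box

    return make_water_box(16, library, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
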