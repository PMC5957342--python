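import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=list(HealthCheck),
)
settings.load_profile("ci")

from densassign.fileio import default_toy_config
from densassign.toy_model import SimulationParams


@pytest.fixture(scope="session")
def toy_config():
    return default_toy_config()


@pytest.fixture(scope="session")
def water(toy_config):
    return toy_config["species_objs"]["toy_water"]


@pytest.fixture(scope="session")
def fluoride(toy_config):
    return toy_config["species_objs"]["toy_fluoride"]


@pytest.fixture(scope="session")
def f85_site(toy_config):
    return toy_config["site_objs"]["f85_like"]


@pytest.fixture(scope="session")
def bulk_site(toy_config):
    return toy_config["site_objs"]["bulk_shell"]


def make_params(**kw):
    defaults = dict(
        temperature=300.0,
        friction=1.0,
        dt=0.002,
        n_steps=10000,
        burn_in_steps=1000,
        seed=0,
        sample_stride=10,
    )
    defaults.update(kw)
    return SimulationParams(**defaults)


@pytest.fixture
def params_factory():
    return make_params
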