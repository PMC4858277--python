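import numpy as np
import pytest
from hypothesis import settings

import staghunt as sh

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> sh.SimConfig:
    return sh.SimConfig()


@pytest.fixture(scope="session")
def desk_config() -> sh.SimConfig:
    return sh.make_config("baseline", "desk")


@pytest.fixture(scope="session")
def tiny_config() -> sh.SimConfig:
    """A very small but structurally complete configuration for fast tests."""
    return sh.make_config("baseline", "desk").replace(
        evo=dict(population_size=4, generations=3, n_partners=2,
                 sims_per_pair=1, episode_steps=300, capture_steps=50,
                 pre_generations=2, n_hares=2, n_stags=2),
    )


@pytest.fixture(scope="session")
def arch() -> sh.ControllerArchitecture:
    return sh.ControllerArchitecture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
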