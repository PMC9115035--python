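import pytest

from ironcycle import build_world, make_fixture_world
from ironcycle.config import WorldConfig


@pytest.fixture(scope="session")
def empty_fixture():
    return make_fixture_world("empty", seed=1)


@pytest.fixture(scope="session")
def single_cluster_fixture():
    return make_fixture_world("single_cluster", seed=1)


@pytest.fixture(scope="session")
def minimal_cycle_fixture():
    return make_fixture_world("minimal_cycle", seed=1)


@pytest.fixture()
def small_world():
    """A 5^3 world with a single compact cluster and one reducer."""
    cfg, _ = make_fixture_world("single_cluster", seed=3)
    return build_world(cfg, seed=3)


@pytest.fixture()
def bare_config():
    """Tiny all-medium config useful for hand-built lattices."""
    return WorldConfig(
        grid_side=5, fe_patch_percentage=0.0, initial_number_fe3reducer=0,
        initial_number_fe2oxidizer=0, initial_number_nanoparticle=0,
        max_ticks=10, np_loss_percentage=0.0,
    )

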