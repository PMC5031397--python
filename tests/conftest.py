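import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_world():
    """A small seeded reference world shared across tests (4 genera x 3
    species x 3 sequences, default divergences, planted default pair)."""
    from minicoi.synthdata import WorldParams, simulate_reference_world
    return simulate_reference_world(WorldParams(seed=11))


@pytest.fixture(scope="session")
def trained_model(small_world):
    from minicoi.classify import train_bayes
    return train_bayes(small_world.library_inserts())


@pytest.fixture(scope="session")
def default_pair():
    from minicoi.primers import builtin_pair
    return builtin_pair()
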