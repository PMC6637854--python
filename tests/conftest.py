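import pytest

from fvgap.synthetic_world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_config():
    """A small but fully structured world: 12 countries, 5 regions, 1990-2050."""
    return WorldConfig(n_countries=12, n_regions=5, start_year=1990, seed=42)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def default_world():
    """The default 20-country world used by the demo pipeline."""
    return generate_world(WorldConfig(seed=7))
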