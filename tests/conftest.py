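import pytest
from hypothesis import settings

from okacycle import KineticParams, SimConfig, make_minicircle

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tpl():
    """Default 409-nt minicircle (200 C : 4 G lagging template)."""
    return make_minicircle(seed=1)


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture
def base_config(tpl):
    return SimConfig(template=tpl, duration=60.0, seed=1)
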