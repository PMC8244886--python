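import pytest
from hypothesis import settings

from hapnetdiv import panel_fixtures, realize

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panels():
    return panel_fixtures()


@pytest.fixture(scope="session")
def fig1a_alignment(panels):
    return realize(panels["fig1A"])


@pytest.fixture(scope="session")
def fig1b_alignment(panels):
    return realize(panels["fig1B"])
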