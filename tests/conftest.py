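import pytest

from chf_telehealth import builtin_defaults


@pytest.fixture(scope="session")
def defaults():
    return builtin_defaults()


@pytest.fixture(scope="session")
def tp(defaults):
    """NYHA II/III hazard column (the base-case stratum)."""
    return defaults.transition("NYHA II or III")


@pytest.fixture(scope="session")
def base(defaults):
    return defaults.scenarios["base"]


@pytest.fixture(scope="session")
def costs(defaults):
    return defaults.costs


@pytest.fixture(scope="session")
def options(defaults):
    return defaults.options
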