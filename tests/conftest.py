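import pytest

from protscape.synthetic_data import generate_community, simulate_psms, small_config


@pytest.fixture(scope="session")
def community():
    return generate_community(small_config(seed=7))


@pytest.fixture(scope="session")
def simulated(community):
    return simulate_psms(community)
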