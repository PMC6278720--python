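import pytest

from macpolnet import all_attractors, macrophage_network


@pytest.fixture(scope="session")
def macnet():
    return macrophage_network()


@pytest.fixture(scope="session")
def census(macnet):
    return all_attractors(macnet)


@pytest.fixture(scope="session")
def steady_states(macnet, census):
    return census.steady_states()


def no_input_assignment(net):
    return {name: 0 for name in net.inputs}
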