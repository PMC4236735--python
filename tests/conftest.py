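import pytest

from kindraft import FixtureSpec, random_consistent_network, toy_branched, toy_linear_chain


@pytest.fixture
def chain3():
    return toy_linear_chain(3, 1.0)


@pytest.fixture
def branched():
    return toy_branched()


@pytest.fixture
def small_random():
    return random_consistent_network(FixtureSpec(n_species=6, n_reactions=9, seed=7))
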