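import pytest

from hemepath import synthetic_data as syn


@pytest.fixture(scope="session")
def bridge_toy():
    """Two hemes joined by a serine bridge: H-bond + 2 covalent + 1 jump."""
    return syn.make_toy_structure("bridge")


@pytest.fixture(scope="session")
def two_route_toy():
    """Two hemes with competing Trp/Phe bridges; Trp route wins."""
    return syn.make_toy_structure("two_route")


@pytest.fixture(scope="session")
def conductive_toy():
    """Single macrocycle; donor/acceptor are two pyrrole rings."""
    return syn.make_toy_structure("conductive")


@pytest.fixture(scope="session")
def o2_short_toy():
    return syn.make_toy_structure("o2_short")


@pytest.fixture(scope="session")
def o2_long_toy():
    return syn.make_toy_structure("o2_long")
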