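import pytest

from thermoefm.classify import classify_efm_set
from thermoefm.efm import enumerate_efms, remove_internal_cycles
from thermoefm.fixtures import make_random_network, make_toy6

# Seeds of the small random networks exercised throughout the suite.
RANDOM_NET_SPECS = [(4, 6, 1), (4, 7, 0), (4, 7, 2), (3, 6, 3), (4, 8, 4)]


@pytest.fixture(scope="session")
def toy6():
    return make_toy6()


@pytest.fixture(scope="session")
def toy6_classified(toy6):
    """TOY6 EFMs after cycle removal, with feasibility labels."""
    efms = remove_internal_cycles(enumerate_efms(toy6.model), "T_A")
    return classify_efm_set(efms, toy6.model, toy6.conc, toy6.thermo)


@pytest.fixture(scope="session", params=RANDOM_NET_SPECS, ids=lambda s: f"net{s[0]}x{s[1]}s{s[2]}")
def random_net(request):
    return make_random_network(*request.param)


@pytest.fixture(scope="session")
def all_fixtures(toy6):
    return [toy6] + [make_random_network(*s) for s in RANDOM_NET_SPECS]


@pytest.fixture(
    scope="session", params=RANDOM_NET_SPECS, ids=lambda s: f"dag{s[0]}x{s[1]}s{s[2]}"
)
def acyclic_net(request):
    """Cycle-free (DAG) variant: LP flux bounds are tight against EFMs."""
    return make_random_network(*request.param, acyclic=True)
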