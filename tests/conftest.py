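import pytest

from veinflow import build_cyrtoloma_network, load_table1
from veinflow.core import solve_nodal


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def wing_network():
    return build_cyrtoloma_network()


@pytest.fixture(scope="session")
def wing_solutions(wing_network):
    """(with-ECV, without-ECV) nodal solutions of the measured wing."""
    with_ecv = solve_nodal(wing_network)
    without_ecv = solve_nodal(wing_network.without_channel("ECV"))
    return with_ecv, without_ecv
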