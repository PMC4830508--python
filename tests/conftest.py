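import pytest

import veinmorph as vm


@pytest.fixture(scope="session")
def lattice3():
    """3x3 periodic unit square lattice (closed-form equilibrium)."""
    return vm.make_fixture("square_lattice", 3)


@pytest.fixture(scope="session")
def small_net():
    """Small hierarchical network, deterministic."""
    return vm.generate_reference_network(20, seed=42)


@pytest.fixture(scope="session")
def optimized_net():
    """100-areole network taken through the thickness optimization."""
    net = vm.generate_reference_network(100, seed=1)
    return vm.optimize_thickness(net)


@pytest.fixture(scope="session")
def equilibrated_small():
    net = vm.generate_reference_network(20, seed=42)
    return vm.equilibrate(net)


def make_single_rod(l=1.02, l0=1.0, h=1.0, mu=300.0, P_tur=0.0):
    """Open two-node network holding one rod of prescribed strain."""
    return vm.VeinNetwork(
        vm.PeriodicBox(10.0, 10.0),
        [1.0, 1.0 + l],
        [1.0, 1.0],
        [0],
        [1],
        [0],
        [0],
        [h],
        [l0],
        mu=mu,
        P_tur=P_tur,
        periodic=False,
    )


@pytest.fixture
def single_rod():
    return make_single_rod()
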