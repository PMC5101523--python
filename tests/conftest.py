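import numpy as np
import pytest

import nnmfmo as nm


@pytest.fixture(scope="session")
def two_node_network():
    """A single spring: two 110 amu nodes 5 Å apart, k2 = k4 = 10."""
    coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
    return nm.build_network(coords, r_cut=10.0, k2=10.0, k4=10.0)


@pytest.fixture(scope="session")
def random_network():
    """A dense, connected random 3-D network (12 nodes in a 12 Å box)."""
    struct = nm.make_toy_structure(n_residues=12, seed=3, box=12.0)
    return nm.build_network(struct, r_cut=10.0, k2=10.0, k4=10.0)


@pytest.fixture(scope="session")
def periodic_chain_spec():
    return nm.FpuChainSpec(n_nodes=32, boundary="periodic", k2=10.0, k4=10.0)


@pytest.fixture(scope="session")
def periodic_chain(periodic_chain_spec):
    return nm.make_fpu_chain(periodic_chain_spec)


@pytest.fixture(scope="session")
def trimer():
    return nm.make_c3_trimer(nm.ToyTrimerSpec(seed=1))


@pytest.fixture(scope="session")
def trimer_network(trimer):
    return nm.build_network(trimer, r_cut=10.0, k2=10.0, k4=10.0)


@pytest.fixture(scope="session")
def trimer_modes(trimer_network):
    return nm.normal_modes(trimer_network)


@pytest.fixture(scope="session")
def monomer_system():
    """One pigment site with a 100 cm⁻¹ mode at S = 0.3."""
    return nm.make_vibronic_fixture(
        "monomer", site_energy=12300.0, mode_frequency=100.0, huang_rhys=0.3
    )
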