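import numpy as np
import pytest

import allowave as aw


@pytest.fixture(scope="session")
def ring_trajectory():
    """6-cycle (two equivalent 2-intermediate bridges), long dense grid."""
    net = aw.make_two_path("I", 1.0, 1.0)
    H = aw.build_tight_binding_hamiltonian(net)
    times = np.linspace(0.0, 2000.0, 100001)
    return aw.evolve_quantum(H, "1", times)


@pytest.fixture(scope="session")
def two_site_trajectory():
    net = aw.make_sc_chain(2, 1.0)
    H = aw.build_tight_binding_hamiltonian(net)
    times = np.linspace(0.0, np.pi, 20001)
    return aw.evolve_quantum(H, "1", times)


def chain_trajectory(N, h=1.0, t_end=None, points=None):
    net = aw.make_sc_chain(N, h)
    H = aw.build_tight_binding_hamiltonian(net)
    t_end = t_end if t_end is not None else 4.0 * N / abs(h)
    points = points or 500 * N
    return aw.evolve_quantum(H, "1", np.linspace(0.0, t_end, points))
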