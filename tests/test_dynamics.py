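"""Quantum and classical propagation: exactness, unitarity, reduction."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

import allowave as aw


def test_two_site_population_is_sin_squared(two_site_trajectory):
    t = two_site_trajectory.times
    P2 = two_site_trajectory.population("2")
    assert np.abs(P2 - np.sin(t) ** 2).max() < 1e-12
    # P_2(pi/2) = 1: complete transfer at a quarter period
    assert P2[np.argmin(np.abs(t - np.pi / 2))] == pytest.approx(1.0, abs=1e-7)


def test_six_cycle_active_site_closed_form(ring_trajectory):
    """P_4(t) = (1/9) (2 sin t - sin 2t)^2 on the 6-cycle, so P_4(2pi/3) = 3/4."""
    t = ring_trajectory.times
    P4 = ring_trajectory.population("4")
    assert np.abs(P4 - (1 / 9) * (2 * np.sin(t) - np.sin(2 * t)) ** 2).max() < 1e-12


def test_three_path_branch_populations_scale_with_coupling_squared():
    """Hub dynamics distribute population over branches as h_{1,j}^2."""
    net = aw.make_three_path("A", 1.0)
    H = aw.build_tight_binding_hamiltonian(net)
    traj = aw.evolve_quantum(H, "1", np.linspace(0, 6, 2001))
    P = traj.populations
    mask = P[:, 1] > 1e-6  # avoid the common zeros of all branch populations
    assert mask.sum() > 1000
    assert np.allclose(P[mask, 2] / P[mask, 1], 0.5, atol=1e-6)
    assert np.allclose(P[mask, 3] / P[mask, 1], 1 / 3, atol=1e-6)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(n=st.integers(2, 6), data=st.data())
def test_unitarity_on_random_networks(n, data):
    sites = [(str(k), data.draw(st.floats(-1, 1))) for k in range(1, n + 1)]
    couplings = [
        (str(k), str(k + 1), data.draw(st.floats(-2, 2).filter(lambda x: x != 0)))
        for k in range(1, n)
    ]
    net = aw.SiteNetwork(sites, couplings, "1", str(n))
    H = aw.build_tight_binding_hamiltonian(net)
    traj = aw.evolve_quantum(H, "1", np.linspace(0, 20, 300))
    assert np.abs(traj.populations.sum(axis=1) - 1.0).max() < 1e-9


def test_time_reversal_returns_the_start_state():
    net = aw.make_sc_chain(7, 1.0)
    H = aw.build_tight_binding_hamiltonian(net)
    t = 13.7
    traj = aw.evolve_quantum(H, "1", np.array([0.0, t]))
    W_t = traj.amplitudes[1]
    back = scipy.linalg.expm(1j * H.matrix * t) @ W_t
    expected = np.zeros(7, dtype=complex)
    expected[0] = 1.0
    assert np.abs(back - expected).max() < 1e-10


def test_stepwise_constant_schedule_matches_exact():
    net = aw.make_sc_chain(5, 1.0)
    H = aw.build_tight_binding_hamiltonian(net)

    traj = aw.evolve_stepwise(lambda t: H, "1", 0.01, 20.0)
    exact = aw.evolve_quantum(H, "1", traj.times)
    assert np.abs(traj.populations - exact.populations).max() < 1e-6


# -- Lanczos ------------------------------------------------------------------


def test_lanczos_full_order_reproduces_spectrum():
    net = aw.make_two_path("III", 1.0, 0.6)
    H = aw.build_tight_binding_hamiltonian(net)
    red = aw.lanczos_reduce(H, "1", H.dim)
    assert np.allclose(
        np.sort(red.eigenvalues()), np.linalg.eigvalsh(H.matrix), atol=1e-8
    )
    # Krylov basis orthonormal
    G = red.basis.conj().T @ red.basis
    assert np.abs(G - np.eye(red.m)).max() < 1e-8
    assert np.all(red.beta >= 0)


def test_lanczos_on_a_chain_recovers_the_chain():
    net = aw.make_sc_chain(6, 0.9)
    H = aw.build_tight_binding_hamiltonian(net)
    red = aw.lanczos_reduce(H, "1", 6)
    assert np.allclose(red.alpha, 0.0, atol=1e-12)
    assert np.allclose(np.abs(red.beta), 0.9, atol=1e-12)


def test_lanczos_eigenvalues_stay_inside_the_spectrum():
    net = aw.make_double_trumpet22(1.0)
    H = aw.build_tight_binding_hamiltonian(net)
    w = np.linalg.eigvalsh(H.matrix)
    red = aw.lanczos_reduce(H, "1", 4)
    ev = red.eigenvalues()
    assert ev.min() >= w.min() - 1e-9 and ev.max() <= w.max() + 1e-9


def test_lanczos_short_time_fidelity_on_the_trumpet():
    """Door-state dynamics of the reduced tridiagonal matrix track the full
    16-site dynamics (the layered trumpet closes on a 5-dim Krylov space)."""
    net = aw.make_trumpet16(1.0)
    H = aw.build_tight_binding_hamiltonian(net)
    red = aw.lanczos_reduce(H, "1", 8)
    assert red.breakdown and red.m == 5
    times = np.linspace(0, 3, 301)
    approx = red.trajectory(times)
    exact = aw.evolve_quantum(H, "1", times)
    err = np.abs(approx.population("1") - exact.population("1")).max()
    assert err < 1e-3


def test_lanczos_fidelity_improves_with_order():
    net = aw.make_two_path("III", 1.0, 0.6)
    H = aw.build_tight_binding_hamiltonian(net)
    times = np.linspace(0, 3, 301)
    exact = aw.evolve_quantum(H, "1", times).population("1")
    errs = []
    for m in (2, 4, 8):
        red = aw.lanczos_reduce(H, "1", m)
        errs.append(np.abs(red.trajectory(times).population("1") - exact).max())
    assert errs[0] > errs[2]
    assert errs[2] < 1e-10


# -- classical comparators ----------------------------------------------------


@pytest.mark.parametrize("N,expected", [(36, 1 / 36), (6, 1 / 6)])
def test_master_chain_scatters_to_uniform(N, expected):
    traj = aw.evolve_master_chain(N, 1.0, 0, np.array([0.0, 1e4]))
    assert np.abs(traj.populations[-1] - expected).max() < 1e-3


def test_master_chain_conserves_probability():
    traj = aw.evolve_master_chain(8, 1.0, 0, np.linspace(0, 50, 101))
    assert np.abs(traj.populations.sum(axis=1) - 1.0).max() < 1e-10
    assert traj.populations.min() >= 0.0


def test_master_chain_contracts_toward_uniform():
    traj = aw.evolve_master_chain(6, 1.0, 0, np.linspace(0, 30, 301))
    d2 = ((traj.populations - 1 / 6) ** 2).sum(axis=1)
    assert np.all(np.diff(d2) <= 1e-12)


def test_kinetic_zero_generator_is_identity():
    P0 = np.array([0.2, 0.5, 0.3])
    traj = aw.evolve_kinetic(np.zeros((3, 3)), P0, np.linspace(0, 5, 11))
    assert np.allclose(traj.populations, P0, atol=1e-14)


def test_kinetic_two_state_stationary_balance():
    k12, k21 = 0.7, 1.9  # rate j<-i convention: K[j,i] = k_{i->j}
    K = np.array([[-k12, k21], [k12, -k21]])
    traj = aw.evolve_kinetic(K, np.array([1.0, 0.0]), np.array([0.0, 200.0]))
    assert traj.populations[-1, 0] == pytest.approx(k21 / (k12 + k21), abs=1e-9)


def test_kinetic_symmetric_generator_goes_uniform():
    K = np.array(
        [[-1.3, 0.8, 0.5], [0.8, -1.5, 0.7], [0.5, 0.7, -1.2]]
    )
    traj = aw.evolve_kinetic(K, np.array([1.0, 0, 0]), np.array([0.0, 500.0]))
    assert np.allclose(traj.populations[-1], 1 / 3, atol=1e-9)


def test_kinetic_rejects_invalid_generators():
    from allowave.network import NetworkValidationError

    with pytest.raises(NetworkValidationError):
        aw.evolve_kinetic(np.array([[0.0, -1.0], [0.0, 1.0]]), [1, 0], [0.0])
    with pytest.raises(NetworkValidationError):
        aw.evolve_kinetic(np.array([[-1.0, 0.0], [0.5, 0.0]]), [1, 0], [0.0])


# -- long-time averages -------------------------------------------------------


@pytest.mark.parametrize("make", [lambda: aw.make_two_path("I", 1.0, 1.0),
                                  lambda: aw.make_sc_chain(5, 1.0)])
def test_spectral_projector_average_matches_time_average(make):
    net = make()
    H = aw.build_tight_binding_hamiltonian(net)
    traj = aw.evolve_quantum(H, net.allosteric, np.linspace(0, 500, 50001))
    eff = aw.transfer_efficiency(traj)
    spectral = aw.stationary_site_average(H, net.allosteric)
    measured = np.array([eff[lab] for lab in traj.labels])
    assert np.abs(measured - spectral).max() < 1e-3
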