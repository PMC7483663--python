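"""Hamiltonian construction, validation and harmonic-mode thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import allowave as aw
from allowave.network import NetworkValidationError


def test_two_site_tight_binding_matrix():
    net = aw.SiteNetwork([("1", 0.0), ("2", 0.0)], [("1", "2", 1.0)], "1", "2")
    H = aw.build_tight_binding_hamiltonian(net)
    assert np.array_equal(H.matrix, [[0.0, 1.0], [1.0, 0.0]])
    assert H.basis_labels == ("1", "2")


@pytest.mark.parametrize("h,c", [(1.0, 0.5), (1.3, 0.37), (2.0, 1.0)])
def test_two_path_iii_matrix_is_the_eight_site_two_path_hamiltonian(h, c):
    """Principal chain with coupling h plus a 4-intermediate bypass with c*h,
    including the corner element (1,8) = c*h."""
    M = aw.build_tight_binding_hamiltonian(aw.make_two_path("III", h, c)).matrix
    E = np.zeros((8, 8))
    for i in range(3):
        E[i, i + 1] = E[i + 1, i] = h
    for a, b in [(0, 7), (7, 6), (6, 5), (5, 4), (4, 3)]:
        E[a, b] = E[b, a] = c * h
    assert np.array_equal(M, E)
    assert M[0, 7] == c * h


def test_one_sided_coupling_list_builds_symmetric_matrix():
    net = aw.SiteNetwork(
        [("a", 0.1), ("b", -0.2), ("c", 0.0)],
        [("a", "b", 0.7), ("a", "c", -0.3)],
        "a",
        "c",
    )
    M = aw.build_tight_binding_hamiltonian(net).matrix
    assert np.array_equal(M, M.T)
    assert M[1, 0] == 0.7 and M[2, 0] == -0.3
    assert np.array_equal(np.diag(M), [0.1, -0.2, 0.0])


@pytest.mark.parametrize(
    "sites,couplings,allo,act,field",
    [
        ([("1", 0), ("1", 0)], [], "1", "1", "sites"),
        ([("1", 0), ("2", 0)], [("1", "2", 1), ("2", "1", 2)], "1", "2", "couplings"),
        ([("1", 0), ("2", 0)], [("1", "3", 1)], "1", "2", "couplings"),
        ([("1", 0), ("2", 0)], [("1", "1", 1)], "1", "2", "couplings"),
        ([("1", 0), ("2", 0)], [], "1", "1", "active"),
        ([("1", 0), ("2", 0)], [], "3", "2", "allosteric"),
    ],
)
def test_validation_errors_name_the_offending_field(sites, couplings, allo, act, field):
    with pytest.raises(NetworkValidationError, match=field):
        aw.SiteNetwork(sites, couplings, allo, act)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n=st.integers(3, 6),
    data=st.data(),
)
def test_random_networks_build_hermitian_hamiltonians(n, data):
    sites = [(str(k), data.draw(st.floats(-2, 2))) for k in range(1, n + 1)]
    pairs = [(str(i), str(j)) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
    chosen = data.draw(st.lists(st.sampled_from(pairs), min_size=1, unique=True))
    couplings = [(i, j, data.draw(st.floats(-3, 3))) for i, j in chosen]
    net = aw.SiteNetwork(sites, couplings, "1", str(n))
    H = aw.build_tight_binding_hamiltonian(net)
    assert np.abs(H.matrix - H.matrix.conj().T).max() <= 1e-12


def test_tight_binding_invariant_under_relabeling():
    """Permuting the site order of the 6-ring conjugates H by the permutation."""
    ring = aw.make_two_path("I", 1.0, 1.0)
    H = aw.build_tight_binding_hamiltonian(ring).matrix
    perm = [2, 0, 4, 1, 5, 3]
    sites = [ring.sites[p] for p in perm]
    net2 = aw.SiteNetwork(sites, ring.couplings, ring.allosteric, ring.active)
    H2 = aw.build_tight_binding_hamiltonian(net2).matrix
    P = np.zeros((6, 6))
    for new, old in enumerate(perm):
        P[new, old] = 1.0
    assert np.allclose(H2, P @ H @ P.T, atol=1e-15)


# -- vibronic -----------------------------------------------------------------


def test_vibronic_with_zero_modes_reduces_to_tight_binding():
    net = aw.make_sc_chain(3, 0.8)
    vib = aw.VibronicSpec([], 4)
    Hv = aw.build_vibronic_hamiltonian(net, vib)
    Ht = aw.build_tight_binding_hamiltonian(net)
    assert np.array_equal(Hv.matrix, Ht.matrix)
    assert Hv.basis_labels == Ht.basis_labels


def test_uncoupled_oscillator_spectrum():
    # uncoupled sites with one g = 0 mode: spectrum is E_j + omega*(n + 1/2)
    site = aw.SiteNetwork([("1", 0.3), ("2", 50.0)], [], "1", "2")
    vib = aw.VibronicSpec([aw.Mode(1.1, {})], 3)
    H = aw.build_vibronic_hamiltonian(site, vib)
    w = np.linalg.eigvalsh(H.matrix)
    expected = sorted(
        e + 1.1 * (n + 0.5) for e in (0.3, 50.0) for n in range(4)
    )
    assert np.allclose(w, expected, atol=1e-12)


def test_displaced_oscillator_ground_state_converges():
    """One site linearly coupled to one mode: E0 -> E + omega/2 - g^2*omega."""
    site = aw.SiteNetwork([("1", 0.2), ("2", 90.0)], [], "1", "2")
    omega, g = 1.0, 0.6
    exact = 0.2 + omega / 2.0 - g * g * omega
    errs = []
    for n_max in (5, 10, 30):
        vib = aw.VibronicSpec([aw.Mode(omega, {"1": g})], n_max)
        H = aw.build_vibronic_hamiltonian(site, vib)
        errs.append(abs(np.linalg.eigvalsh(H.matrix)[0] - exact))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-10


def test_vibronic_uncoupled_spectrum_is_sum_of_blocks():
    """With all g = 0 the spectrum is every electronic + oscillator sum."""
    net = aw.make_sc_chain(2, 0.9)
    vib = aw.VibronicSpec([aw.Mode(1.3, {"1": 0.0, "2": 0.0})], 2)
    H = aw.build_vibronic_hamiltonian(net, vib)
    w = np.sort(np.linalg.eigvalsh(H.matrix))
    el = np.linalg.eigvalsh(aw.build_tight_binding_hamiltonian(net).matrix)
    osc = [1.3 * (n + 0.5) for n in range(3)]
    expected = np.sort([e + o for e in el for o in osc])
    assert np.allclose(w, expected, atol=1e-12)


def test_vibronic_hamiltonians_are_hermitian_and_sized():
    net = aw.make_sc_chain(3, 1.0)
    vib = aw.VibronicSpec([aw.Mode(1.0, {"1": 0.4}), aw.Mode(2.0, {"3": -0.2})], 2)
    H = aw.build_vibronic_hamiltonian(net, vib)
    assert H.dim == 3 * 3 * 3
    assert np.abs(H.matrix - H.matrix.conj().T).max() <= 1e-12


def test_negative_truncation_rejected():
    with pytest.raises(NetworkValidationError, match="n_max"):
        aw.VibronicSpec([aw.Mode(1.0, {})], -1)


# -- harmonic-oscillator thermodynamics ---------------------------------------


@pytest.mark.parametrize("omega,T", [(1.0, 0.5), (2.5, 1.7), (0.3, 10.0)])
def test_entropy_identity_and_energy_derivative(omega, T):
    Q, E, S = aw.harmonic_thermo(omega, T)
    assert S == pytest.approx(math.log(Q) + E / T, abs=1e-12)
    # independent oracle: E = -d ln Q / d beta by central difference
    beta = 1.0 / T
    db = 1e-6 * beta

    def lnQ(b):
        return -b * omega / 2.0 - math.log(1.0 - math.exp(-b * omega))

    E_num = -(lnQ(beta + db) - lnQ(beta - db)) / (2.0 * db)
    assert E == pytest.approx(E_num, rel=1e-7)


def test_harmonic_thermo_limits():
    # ground-state limit: beta*omega large
    _, E, S = aw.harmonic_thermo(5.0, 0.05)
    assert E == pytest.approx(2.5, abs=1e-10)
    assert S == pytest.approx(0.0, abs=1e-10)
    # classical limit: beta*omega small -> E ~ k_B T
    _, E, _ = aw.harmonic_thermo(0.001, 10.0)
    assert E == pytest.approx(10.0, rel=1e-3)


def test_harmonic_thermo_domain_errors():
    with pytest.raises(ValueError):
        aw.harmonic_thermo(1.0, 0.0)
    with pytest.raises(ValueError):
        aw.harmonic_thermo(-1.0, 1.0)


def test_wavenumber_conversion_default_reference():
    assert aw.from_wavenumbers(1000.0) == 1.0
    assert aw.from_wavenumbers(100.0) == pytest.approx(0.1)
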