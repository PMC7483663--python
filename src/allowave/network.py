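"""Site networks and their Hamiltonians.

A macromolecule is reduced to a network of sites: each site carries one
electronic state with an energy, and undirected weighted couplings connect
pairs of sites.  A perturbation created at the allosteric (sensor) site
propagates over this network; the active site is where the wave is
characterized.  Internal units set hbar = 1 and k_B = 1: energies and
couplings are dimensionless and time is measured in 1/|h| for a reference
coupling h.

Two Hamiltonians can be built from a network:

* a tight-binding (purely electronic) Hamiltonian, with site energies on
  the diagonal and couplings off the diagonal;
* a vibronic Hamiltonian, in which every site is additionally coupled
  linearly (and diagonally in the electronic index) to a set of shared
  harmonic modes, expanded on a truncated oscillator product basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "Site",
    "Coupling",
    "SiteNetwork",
    "Mode",
    "VibronicSpec",
    "Hamiltonian",
    "NetworkValidationError",
    "build_tight_binding_hamiltonian",
    "build_vibronic_hamiltonian",
    "harmonic_thermo",
    "from_wavenumbers",
]

HERMITICITY_RTOL = 1e-12


class NetworkValidationError(ValueError):
    """Raised when a network or Hamiltonian specification is inconsistent."""


@dataclass(frozen=True)
class Site:
    id: str
    energy: float = 0.0


@dataclass(frozen=True)
class Coupling:
    i: str
    j: str
    h: float


@dataclass(frozen=True)
class SiteNetwork:
    """A network of coupled sites with designated allosteric and active sites.

    Site ids must be unique; couplings are undirected, self-couplings are
    forbidden and each unordered pair may appear at most once.
    """

    sites: tuple[Site, ...]
    couplings: tuple[Coupling, ...]
    allosteric: str
    active: str

    def __init__(self, sites, couplings, allosteric, active):
        object.__setattr__(
            self, "sites", tuple(s if isinstance(s, Site) else Site(*s) for s in sites)
        )
        object.__setattr__(
            self,
            "couplings",
            tuple(c if isinstance(c, Coupling) else Coupling(*c) for c in couplings),
        )
        object.__setattr__(self, "allosteric", allosteric)
        object.__setattr__(self, "active", active)
        self._validate()

    def _validate(self) -> None:
        ids = [s.id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise NetworkValidationError("sites: duplicate site id")
        known = set(ids)
        if self.allosteric not in known:
            raise NetworkValidationError(
                f"allosteric: unknown site id {self.allosteric!r}"
            )
        if self.active not in known:
            raise NetworkValidationError(f"active: unknown site id {self.active!r}")
        if self.allosteric == self.active:
            raise NetworkValidationError(
                "active: allosteric and active sites must be distinct"
            )
        seen: set[frozenset[str]] = set()
        for c in self.couplings:
            if c.i not in known:
                raise NetworkValidationError(f"couplings: unknown site id {c.i!r}")
            if c.j not in known:
                raise NetworkValidationError(f"couplings: unknown site id {c.j!r}")
            if c.i == c.j:
                raise NetworkValidationError(
                    f"couplings: self-coupling on site {c.i!r}"
                )
            key = frozenset((c.i, c.j))
            if key in seen:
                raise NetworkValidationError(
                    f"couplings: duplicate pair ({c.i!r}, {c.j!r})"
                )
            seen.add(key)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sites)

    def index(self, site_id: str) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError:
            raise NetworkValidationError(f"unknown site id {site_id!r}") from None

    def coupling_matrix(self) -> np.ndarray:
        """Dense symmetric matrix of couplings (zero diagonal)."""
        n = self.n_sites
        idx = {s: k for k, s in enumerate(self.site_ids)}
        V = np.zeros((n, n))
        for c in self.couplings:
            a, b = idx[c.i], idx[c.j]
            V[a, b] = V[b, a] = c.h
        return V

    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.sites], dtype=float)

    def max_coupling(self) -> float:
        return max((abs(c.h) for c in self.couplings), default=0.0)

    def with_couplings(self, values: dict[frozenset, float]) -> "SiteNetwork":
        """Copy of the network with some coupling values replaced."""
        new = [
            Coupling(c.i, c.j, values.get(frozenset((c.i, c.j)), c.h))
            for c in self.couplings
        ]
        return SiteNetwork(self.sites, new, self.allosteric, self.active)


@dataclass(frozen=True)
class Mode:
    """One shared harmonic mode: frequency and per-site linear couplings."""

    omega: float
    g: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class VibronicSpec:
    """Shared harmonic modes diagonally coupled to the electronic sites.

    ``n_max`` is the highest oscillator quantum number kept per mode; the
    product basis then has ``(n_max + 1)**n_modes`` oscillator states per
    electronic site.
    """

    modes: tuple[Mode, ...]
    n_max: int

    def __init__(self, modes, n_max):
        object.__setattr__(
            self, "modes", tuple(m if isinstance(m, Mode) else Mode(*m) for m in modes)
        )
        object.__setattr__(self, "n_max", int(n_max))
        if self.n_max < 0:
            raise NetworkValidationError("n_max: must be >= 0")
        for k, m in enumerate(self.modes):
            if not m.omega > 0:
                raise NetworkValidationError(f"modes[{k}].omega: must be > 0")


@dataclass(frozen=True)
class Hamiltonian:
    """Hermitian matrix over a labeled basis."""

    matrix: np.ndarray
    basis_labels: tuple[str, ...]

    def __post_init__(self):
        M = np.asarray(self.matrix)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise NetworkValidationError("matrix: must be square")
        if M.shape[0] != len(self.basis_labels):
            raise NetworkValidationError("basis_labels: length must match matrix")
        scale = max(np.abs(M).max(), 1.0)
        if np.abs(M - M.conj().T).max() > HERMITICITY_RTOL * scale:
            raise NetworkValidationError("matrix: not Hermitian")
        object.__setattr__(self, "matrix", M)
        object.__setattr__(self, "basis_labels", tuple(self.basis_labels))

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def index(self, label: str) -> int:
        try:
            return self.basis_labels.index(label)
        except ValueError:
            raise NetworkValidationError(f"unknown basis label {label!r}") from None


def build_tight_binding_hamiltonian(network: SiteNetwork) -> Hamiltonian:
    """Electronic Hamiltonian: site energies on the diagonal, couplings off it."""
    H = network.coupling_matrix().astype(float)
    np.fill_diagonal(H, network.energies())
    return Hamiltonian(H, network.site_ids)


def _oscillator_ladder(n_max: int) -> np.ndarray:
    """b + b^dagger on the 0..n_max number basis."""
    n = n_max + 1
    X = np.zeros((n, n))
    for k in range(n - 1):
        X[k, k + 1] = X[k + 1, k] = math.sqrt(k + 1)
    return X


def build_vibronic_hamiltonian(network: SiteNetwork, vib: VibronicSpec) -> Hamiltonian:
    """Exciton-bath Hamiltonian with diagonal linear coupling.

    H = sum_j E_j |s_j><s_j|  +  sum_{j!=k} V_jk |s_j><s_k|
      + sum_{j,l} omega_l g_{j,l} (b_l + b_l^+) |s_j><s_j|
      + sum_l omega_l (b_l^+ b_l + 1/2)

    expanded on the site (x) truncated-oscillator product basis.  Basis order
    is site-major; the oscillator quanta run in mixed-radix order with the
    last mode fastest, so matrices are bit-reproducible.
    """
    n_sites = network.n_sites
    n_modes = len(vib.modes)
    Hel = build_tight_binding_hamiltonian(network).matrix
    if n_modes == 0:
        return Hamiltonian(Hel, network.site_ids)

    d = vib.n_max + 1
    osc_dim = d**n_modes
    I_osc = np.eye(osc_dim)
    X = _oscillator_ladder(vib.n_max)
    num = np.diag(np.arange(d, dtype=float))

    def lift(op: np.ndarray, mode: int) -> np.ndarray:
        """Embed a single-mode operator in the oscillator product space."""
        out = np.eye(1)
        for l in range(n_modes):
            out = np.kron(out, op if l == mode else np.eye(d))
        return out

    H = np.kron(Hel, I_osc)
    # free-bath term, shared by every electronic site
    H_bath = sum(
        m.omega * (lift(num, l) + 0.5 * I_osc) for l, m in enumerate(vib.modes)
    )
    H += np.kron(np.eye(n_sites), H_bath)
    # diagonal linear exciton-bath coupling
    for j, site in enumerate(network.sites):
        proj = np.zeros((n_sites, n_sites))
        proj[j, j] = 1.0
        coup = sum(
            m.omega * m.g.get(site.id, 0.0) * lift(X, l)
            for l, m in enumerate(vib.modes)
        )
        if np.any(coup):
            H += np.kron(proj, coup)

    labels = tuple(
        f"{s.id}|n=" + ",".join(str(q) for q in quanta)
        for s in network.sites
        for quanta in product(range(d), repeat=n_modes)
    )
    return Hamiltonian(H, labels)


def harmonic_thermo(omega: float, T: float) -> tuple[float, float, float]:
    """Partition function, mean energy and entropy of one harmonic mode.

    Q = exp(-beta*omega/2) / (1 - exp(-beta*omega)) with beta = 1/(k_B T),
    E = -d ln Q / d beta in closed form, S = k_B ln Q + E/T (k_B = 1).
    """
    if not omega > 0:
        raise ValueError("omega must be > 0")
    if not T > 0:
        raise ValueError("T must be > 0")
    beta = 1.0 / T
    x = beta * omega
    Q = math.exp(-x / 2.0) / (1.0 - math.exp(-x))
    E = omega / 2.0 + omega / math.expm1(x)
    S = math.log(Q) + E / T
    return Q, E, S


def from_wavenumbers(value_cm1: float, reference_cm1: float = 1000.0) -> float:
    """Convert an energy in cm^-1 to internal dimensionless units.

    The reference energy maps to 1; the default (1000 cm^-1) makes a typical
    intra-group coupling h = 1 and a 10% inter-group coupling (100 cm^-1) 0.1.
    """
    if not reference_cm1 > 0:
        raise ValueError("reference_cm1 must be > 0")
    return value_cm1 / reference_cm1
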