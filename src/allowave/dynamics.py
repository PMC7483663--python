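"""Time evolution of the perturbation wave.

Quantum dynamics follow W(t) = exp(-iHt) W(0) (hbar = 1) with populations
P_i(t) = |W_i(t)|^2.  For a constant Hamiltonian the propagator is applied
through one eigendecomposition, which is exact on the stored grid.  For
time-dependent couplings a piecewise-constant exponential midpoint stepper
is provided.  Large sparse Hamiltonians can be reduced to a small
tridiagonal matrix by the Lanczos procedure from the door-state, valid for
short-time dynamics.  Classical comparators propagate a master equation
(a continuous-time random walk on the chain) or a general rate matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .network import Hamiltonian, NetworkValidationError

__all__ = [
    "Trajectory",
    "TridiagonalReduction",
    "NormDriftWarning",
    "evolve_quantum",
    "evolve_stepwise",
    "lanczos_reduce",
    "evolve_master_chain",
    "evolve_kinetic",
    "stationary_site_average",
    "default_time_grid",
]

NORM_TOL = 1e-9
NORM_DRIFT_TOL = 1e-6


class NormDriftWarning(UserWarning):
    """Total probability drifted more than expected during a stepwise run."""


@dataclass
class Trajectory:
    """Populations (and, for quantum runs, amplitudes) on a time grid."""

    times: np.ndarray
    populations: np.ndarray  # shape (n_times, n_basis)
    labels: tuple[str, ...]
    amplitudes: np.ndarray | None = None  # complex, quantum runs only
    kind: str = "quantum"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        self.labels = tuple(self.labels)
        if self.populations.shape != (self.times.size, len(self.labels)):
            raise ValueError("populations shape must be (n_times, n_labels)")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    def population(self, label: str) -> np.ndarray:
        return self.populations[:, self.index(label)]

    def site_populations(self, site_ids: Sequence[str]) -> np.ndarray:
        """Populations summed over all basis labels belonging to each site.

        Vibronic basis labels are "<site>|n=..."; plain labels are site ids.
        """
        out = np.zeros((self.times.size, len(site_ids)))
        for k, sid in enumerate(site_ids):
            cols = [
                j
                for j, lab in enumerate(self.labels)
                if lab == sid or lab.startswith(sid + "|")
            ]
            if not cols:
                raise KeyError(f"no basis labels for site {sid!r}")
            out[:, k] = self.populations[:, cols].sum(axis=1)
        return out


def default_time_grid(n_sites: int, h: float = 1.0, points: int = 2000) -> np.ndarray:
    """Grid [0, 4*N/|h|] capturing the first passage of all bundled models."""
    return np.linspace(0.0, 4.0 * n_sites / abs(h), points)


def _start_vector(H: Hamiltonian, start: str | int) -> np.ndarray:
    idx = start if isinstance(start, (int, np.integer)) else H.index(start)
    W0 = np.zeros(H.dim, dtype=complex)
    W0[idx] = 1.0
    return W0


def evolve_quantum(
    H: Hamiltonian, start: str | int, times: np.ndarray
) -> Trajectory:
    """Exact propagation of a localized start state under a constant H."""
    times = np.asarray(times, dtype=float)
    w, U = np.linalg.eigh(H.matrix)
    coef = U.conj().T @ _start_vector(H, start)
    phases = np.exp(-1j * np.outer(times, w))
    W = (phases * coef) @ U.T  # (n_times, dim)
    P = np.abs(W) ** 2
    norms = P.sum(axis=1)
    if np.abs(norms - 1.0).max() > NORM_TOL:
        warnings.warn("probability not conserved beyond 1e-9", NormDriftWarning)
    return Trajectory(times, P, H.basis_labels, amplitudes=W, kind="quantum")


def evolve_stepwise(
    H_of_t: Callable[[float], Hamiltonian],
    start: str | int,
    dt: float,
    t_end: float,
) -> Trajectory:
    """Piecewise-constant propagation for a time-dependent Hamiltonian.

    Each step applies exp(-i H(t + dt/2) dt), the exponential midpoint rule;
    for a constant schedule this reduces to the exact propagator up to the
    step discretization of the grid.  Probability is conserved to rounding
    at every step (each factor is unitary); drift beyond 1e-6 triggers a
    NormDriftWarning with diagnostics.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    H0 = H_of_t(0.0)
    labels = H0.basis_labels
    n_steps = int(np.ceil(t_end / dt - 1e-12))
    W = _start_vector(H0, start)
    times = np.arange(n_steps + 1) * dt
    Ws = np.empty((n_steps + 1, H0.dim), dtype=complex)
    Ws[0] = W
    for k in range(n_steps):
        Hk = H_of_t((k + 0.5) * dt)
        w, U = np.linalg.eigh(Hk.matrix)
        W = U @ (np.exp(-1j * w * dt) * (U.conj().T @ W))
        Ws[k + 1] = W
    P = np.abs(Ws) ** 2
    drift = np.abs(P.sum(axis=1) - 1.0).max()
    if drift > NORM_DRIFT_TOL:
        warnings.warn(
            f"norm drift {drift:.3e} over {n_steps} steps (dt={dt})",
            NormDriftWarning,
        )
    traj = Trajectory(times, P, labels, amplitudes=Ws, kind="quantum")
    traj.metadata.update(dt=dt, norm_drift=float(drift))
    return traj


@dataclass
class TridiagonalReduction:
    """Lanczos tridiagonalization of a Hamiltonian from a door-state."""

    alpha: np.ndarray  # diagonal, length m
    beta: np.ndarray  # off-diagonal, length m-1, all >= 0
    basis: np.ndarray  # orthonormal Krylov vectors, shape (dim, m)
    labels: tuple[str, ...]
    breakdown: bool = False  # terminated early on an invariant subspace

    @property
    def m(self) -> int:
        return self.alpha.size

    def matrix(self) -> np.ndarray:
        T = np.diag(self.alpha).astype(float)
        idx = np.arange(self.m - 1)
        T[idx, idx + 1] = T[idx + 1, idx] = self.beta
        return T

    def eigenvalues(self) -> np.ndarray:
        return scipy.linalg.eigh_tridiagonal(self.alpha, self.beta)[0]

    def trajectory(self, times: np.ndarray) -> Trajectory:
        """Approximate dynamics of the door-state mapped back to the full basis."""
        w, V = scipy.linalg.eigh_tridiagonal(self.alpha, self.beta)
        coef = V[0].conj()  # door-state is the first Krylov vector
        phases = np.exp(-1j * np.outer(np.asarray(times, float), w))
        Wk = (phases * coef) @ V.T  # Krylov-space amplitudes
        W = Wk @ self.basis.T
        return Trajectory(times, np.abs(W) ** 2, self.labels, amplitudes=W)


def lanczos_reduce(
    H: Hamiltonian, door_state: str | int, m: int, breakdown_tol: float = 1e-10
) -> TridiagonalReduction:
    """Lanczos with full reorthogonalization from the door-state.

    A vanishing off-diagonal coefficient means the Krylov space closed on an
    invariant subspace; the reduction is then exact and terminates early
    with ``breakdown=True``.
    """
    if not 1 <= m <= H.dim:
        raise ValueError("m must satisfy 1 <= m <= dim(H)")
    A = H.matrix
    scale = max(np.abs(A).max(), 1.0)
    q = _start_vector(H, door_state)
    Q = np.zeros((H.dim, m), dtype=complex)
    alpha = np.zeros(m)
    beta = np.zeros(max(m - 1, 0))
    Q[:, 0] = q
    breakdown = False
    k_eff = m
    for k in range(m):
        v = A @ Q[:, k]
        alpha[k] = np.real(np.vdot(Q[:, k], v))
        v -= alpha[k] * Q[:, k]
        if k > 0:
            v -= beta[k - 1] * Q[:, k - 1]
        # full reorthogonalization (twice is enough)
        for _ in range(2):
            v -= Q[:, : k + 1] @ (Q[:, : k + 1].conj().T @ v)
        if k == m - 1:
            break
        b = np.linalg.norm(v)
        if b <= breakdown_tol * scale:
            breakdown = True
            k_eff = k + 1
            break
        beta[k] = b
        Q[:, k + 1] = v / b
    return TridiagonalReduction(
        alpha[:k_eff].copy(),
        beta[: max(k_eff - 1, 0)].copy(),
        Q[:, :k_eff].copy(),
        H.basis_labels,
        breakdown=breakdown,
    )


def _chain_generator(N: int, h: float) -> np.ndarray:
    """Rate matrix of the nearest-neighbor hopping master equation."""
    K = np.zeros((N, N))
    for i in range(N - 1):
        K[i, i + 1] = K[i + 1, i] = h
    np.fill_diagonal(K, -K.sum(axis=0))
    return K


def evolve_master_chain(
    N: int, h: float, start: int, times: np.ndarray
) -> Trajectory:
    """Classical master equation on the degenerate chain.

    dP_i/dt = h P_{i-1} - 2h P_i + h P_{i+1}, end sites losing only to their
    single neighbor.  The long-time limit is the uniform distribution 1/N.
    ``start`` is a 0-based site index.
    """
    if N < 2:
        raise NetworkValidationError("N: chain needs at least 2 sites")
    if not h > 0:
        raise NetworkValidationError("h: hopping rate must be > 0")
    P0 = np.zeros(N)
    P0[start] = 1.0
    return evolve_kinetic(_chain_generator(N, h), P0, times)


def evolve_kinetic(
    rate_matrix: np.ndarray, P0: np.ndarray, times: np.ndarray
) -> Trajectory:
    """P(t) = exp(Kt) P0 for a generator K (columns sum to zero).

    Off-diagonal entries are rates and must be nonnegative.
    """
    K = np.asarray(rate_matrix, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise NetworkValidationError("rate_matrix: must be square")
    n = K.shape[0]
    off = K - np.diag(np.diag(K))
    if off.min() < 0:
        raise NetworkValidationError("rate_matrix: off-diagonal rates must be >= 0")
    colsums = np.abs(K.sum(axis=0)).max()
    if colsums > 1e-9 * max(np.abs(K).max(), 1.0):
        raise NetworkValidationError("rate_matrix: columns must sum to zero")
    P0 = np.asarray(P0, dtype=float)
    if P0.shape != (n,) or P0.min() < 0 or abs(P0.sum() - 1.0) > 1e-9:
        raise NetworkValidationError("P0: must be a distribution over states")
    times = np.asarray(times, dtype=float)
    P = np.empty((times.size, n))
    # exact exponential of the generator at each stored time (no stepping)
    for k, t in enumerate(times):
        P[k] = scipy.linalg.expm(K * t) @ P0
    P = np.clip(P, 0.0, None)
    labels = tuple(str(i + 1) for i in range(n))
    return Trajectory(times, P, labels, kind="classical")


def stationary_site_average(
    H: Hamiltonian, start: str | int, degeneracy_tol: float = 1e-9
) -> np.ndarray:
    """Infinite-time average populations via spectral projectors.

    <P_a> = sum over distinct eigenvalues E of |<a| Pi_E |start>|^2, with
    eigenvalues closer than ``degeneracy_tol`` grouped before projecting.
    """
    w, U = np.linalg.eigh(H.matrix)
    W0 = _start_vector(H, start)
    coef = U.conj().T @ W0  # overlap of the start state with eigenvectors
    out = np.zeros(H.dim)
    k = 0
    while k < H.dim:
        j = k
        while j + 1 < H.dim and w[j + 1] - w[k] < degeneracy_tol:
            j += 1
        amp = U[:, k : j + 1] @ coef[k : j + 1]
        out += np.abs(amp) ** 2
        k = j + 1
    return out
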