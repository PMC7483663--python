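# Methods

## Model and units

A macromolecule is coarse-grained into N sites with one electronic state
each. Internal units set ħ = 1 and k_B = 1; site energies E_j and
couplings V_jk are dimensionless and time is measured in 1/|h| for a
reference coupling h (for degenerate chains with h = 1 the degenerate-pair
transfer period is π, offered as an output time unit via `--time-unit pi`).
Energies quoted in cm⁻¹ can be mapped to internal units with
`from_wavenumbers`, whose default reference (1000 cm⁻¹ → 1) makes a 10%
inter-group coupling of 100 cm⁻¹ equal 0.1.

The tight-binding Hamiltonian has E_j on the diagonal and V_jk off it.
The vibronic Hamiltonian adds M shared harmonic modes with per-site linear
couplings, diagonal in the electronic index:

    H += Σ_{j,l} ω_l g_{j,l} (b_l + b_l†)|s_j⟩⟨s_j| + Σ_l ω_l (b_l† b_l + ½)

on a product basis truncated at quantum number n_max per mode. Modes are
shared across sites with per-site couplings g_{j,l}; a site-local bath is
recovered by zeroing g elsewhere. Basis order is site-major with mode
quanta in mixed-radix order (last mode fastest), fixed so matrices are
bit-reproducible. Off-diagonal exciton–bath coupling and Duschinsky
rotation are out of scope. The displaced-oscillator closed form (ground
energy E + ω/2 − g²ω for a single site) is the convergence check for the
truncation.

Harmonic-mode thermodynamics use the closed forms
Q = e^(−βω/2)/(1 − e^(−βω)), E = ω/2 + ω/(e^(βω) − 1), S = ln Q + E/T.

## Propagation

For constant H the propagator is applied through one eigendecomposition,
W(t) = U e^(−iΛt) U† W(0) — exact on the stored grid and cheap for the
dense fixtures bundled here (≤ 22 sites; the default characterization grid
is [0, 4N/|h|] with 500 points per site, which captures the first passage
of every bundled model).

Time-dependent couplings use a piecewise-constant exponential midpoint
stepper: each step applies exp(−iH(t+dt/2)·dt), and for population-coupled
chains the midpoint coupling is predicted by a half-step. Every factor is
unitary, so probability is conserved to rounding; drift beyond 1e-6
triggers a warning. The scheme is second order: at the default step
dt = 0.005/max|h|, halving dt changes the active-site populations of the
10-site chains by < 1e-7.

The Lanczos reduction runs with full reorthogonalization (applied twice)
from the door-state. A vanishing off-diagonal coefficient signals that the
Krylov space closed on an invariant subspace — the reduction is then exact
and terminates early, flagged `breakdown`. The layered trumpet systems
close after one vector per layer, which is why their dynamics coincide
with the effective-chain dynamics (below).

Classical comparators integrate dP/dt = K P by the exact matrix
exponential of the generator at each stored time, not by stepping. The
chain master equation uses the symmetric nearest-neighbor generator with
reflecting end rows.

## First-passage characterization

t_a and A_a are the position and height of the first qualifying local
maximum of P_a(t), refined by a three-point parabola (sub-grid accuracy;
on the two-site system the closed forms are recovered to better than
1e-6). A peak qualifies if its height is at least 5% of the trajectory's
global maximum at that site, which guards against numerical ripples.

B_a is the measured full width of the peak at 2/3 of its height (linear
interpolation of the crossings). For a true Gaussian of width parameter
c3 this equals 2·c3·√(ln 1.5); on the two-site system it reproduces the
tetrahedral-angle expression π(180 − 109.471)/180 ≈ 1.2309 exactly. A
generic Gaussian c1·exp(−(t−c2)²/c3²) is additionally least-squares fitted
over the window [t_a − c4, t_a + c4], with c4 the distance to the nearer
1%-of-peak crossing; its parameters and residual RMS are stored as a shape
diagnostic, and a residual above 5% of A_a flags the wave as non-Gaussian
(as happens for the strongly coupling-decreasing regime x = −0.8). The
reported amplitude is the refined raw peak height, not the fitted c1: the
free fit overshoots the height of non-Gaussian lobes by a few percent and
would break the exact two-site limit A_a = 1.

Two-timescale systems — the grouped 20-state models — deliver the wave as
a train of fast pulses (intra-group period) under a slow envelope
(inter-group period), with P_a returning to ≈ 0 between pulses. There the
"first peak of the wave" is the first crest of the pulse train: `envelope`
mode collects the heights of the qualifying raw peaks and selects the
first local maximum of that height sequence whose prominence (within the
sequence) is at least 20% of the largest pulse, falling back to the
highest pulse for monotone trains. On single-lobe waves envelope mode
reduces to raw mode. Raw mode remains the default; the grouped-system
numbers quoted anywhere by this package use envelope mode.

Transfer efficiency is the trapezoidal time average of each site's
population over [0, τ]. Convergence is assessed by successive doublings
of the averaging window inside the trajectory (τ/8 → τ/4 → τ/2 → τ); the
report is converged when the final doubling changes every average by less
than 1e-3. Because the averages of a finite quantum system oscillate with
residual ~1/τ, τ of order 10³ (h = 1) is typically needed for the flag —
the independent spectral-projector formula (eigenvalues grouped at
|ΔE| < 1e-9 before projecting) gives the exact τ → ∞ limit and is used as
the cross-check in the tests.

## Scaling fits

For chains N = 4..15 each of t_a, A_a, B_a is fitted with an ordinary
least-squares quadratic a1 + a2·N + a3·N² on integer N, unweighted.
Per-N signatures flagged non-Gaussian are kept (fit precision is known to
degrade for coupling-decreasing schedules). The Markovian amplitude
quadratic lands within a few percent of the reference coefficients; the
residual offset (~2% on a1) traces to the amplitude convention above
(refined raw peak vs fitted c1).

## Non-Markovian and stochastic couplings

Population-coupled chains update every consecutive coupling each step as
h_{i,i+1} = (1 + x·P)·h. The population P entering the rule is that of
the **downstream** site i+1 (at the step midpoint). This choice is
deliberate: it reproduces the reference arrival-time quadratics of all
four regimes (su/sd/lu/ld) to a few percent *and* the amplitude ordering
A_a(lu) < A_a(su) < A_a(sd) < A_a(ld) at N = 10, whereas feeding the
upstream population inverts the amplitude ordering. Physically the
downstream rule means a bond stiffens (or softens) as the perturbation
arrives at its far end. `population_basis="upstream"` is available for
comparison.

Random environmental modulation fires at deterministic event times, every
(period / events_per_period) with period π/max|h|, so that event
frequencies of 1/8, 1/4 and 1 per period are exactly those rates;
randomness lives only in which edges are hit and by how much. At each
event a subset of ⌈fraction·n_edges⌉ edges is drawn and each selected
edge is set to its base value plus a uniform draw in ±amplitude·h_edge
(additive, not cumulative; edges revert at the next event unless
`persist=True`). Optional candidate long-range pairs (base value 0) join
the pool, so "new non-sequential couplings" and "modified sequential
couplings" are not distinguished. The RNG is numpy's seeded PCG64
(`default_rng`); the seed is mandatory and echoed in trajectory metadata,
and identical seeds give bit-identical trajectories.

## Model library conventions

Sites are numbered 1-based in generation order; the perturbation starts at
"1" and the active site is the last site. Second paths in the two-path
systems are numbered from the active end (1 − n − ... − 5 − 4), matching
the reference 8-site Hamiltonian with corner element (1,8) = c·h entry by
entry.

The trumpet systems specify only layer-to-layer effective couplings
(the cascade √(h/2), √(prev/2), ..., closing with √(h/8) for the 16-site
trumpet; the 22-site double trumpet mirrors the first three values). The
printed cascade — a square root of a coupling — is implemented exactly as
stated. Each physical edge between layers k and k+1 carries the uniform
value h_eff·√(m_k·m_{k+1})/n_edges, which makes the coupling between the
layers' symmetric superposition states equal h_eff exactly for splits and
merges alike; with that choice the full trumpet dynamics, projected on
layers, coincide with the effective-chain dynamics to numerical precision
(the Krylov space from the door-state is exactly the chain of layer
bright states).

The grouped 20-state systems use sequential intra-group coupling h = 1 and
inter-group coupling 0.1·h, either bridging last-of-group to
first-of-next-group or all-to-all between adjacent groups.

## What the generators do and do not emulate

The bundled systems are idealized: degenerate sites, uniform couplings,
no static disorder, no dephasing or dissipation, and coherence preserved
indefinitely. Passing tests therefore demonstrate the coherent-transport
phenomenology (near-lossless first passage, interference between paths,
pulse-train arrival through weakly coupled groups, robustness to moderate
coupling noise) — not quantitative predictions for any real protein, whose
site energies, couplings and bath would first have to be parameterized
from structure or spectroscopy. Mapping real structures to site networks,
open-system (Lindblad/HEOM) dynamics and temperature-dependent dephasing
are out of scope.

## Known limitations

* The B_a(N) trend of the measured 2/3-height width grows with N for
  Markovian chains, while the reference quadratic for B_a decreases; the
  two-site closed form is reproduced exactly, so the discrepancy lies in
  the width convention of the reference fit, which is not fully specified.
  B_a comparisons across conventions should therefore use the two-site
  limit, not the chain quadratic.
* The closed-form B_a of the degenerate pair scales as 1/|h| (the width of
  sin²(ht) at 2/3 height); the package reports the measured width and
  makes no attempt to impose a different h-scaling.
* Peak qualification thresholds (5% height floor, 20% envelope
  prominence) are heuristics; pathological trajectories between the
  single-lobe and pulse-train regimes may need an explicit mode choice.
* `evolve_kinetic` computes one dense matrix exponential per stored time,
  which is exact but not meant for very large state spaces.
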