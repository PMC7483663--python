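# allowave

Time-dependent quantum simulation of allosteric signal propagation on site
networks.

## The problem

Allostery is regulation at a distance: a ligand binding at one site of a
macromolecule (the allosteric or sensor site) alters the function of a
distant active site, often 30-40 Å away. Reduced to a network of coupled
sites (residues, domains, or fragments), the question becomes how a
perturbation created at one node can travel to a specific distant node
*without* dissolving into the countless degrees of freedom in between — a
classical hopping (master-equation) picture spreads the perturbation
uniformly over all N sites, destroying the preferential sensor-to-active
relationship. Treated as a quantum wave, the same perturbation moves
coherently along the network and arrives at the active site nearly intact,
the mechanism long established for exciton transport in photosynthetic
light-harvesting complexes such as FMO.

`allowave` is a small toolkit for studying that picture quantitatively. It
is intended for researchers modelling signal or energy transfer on
coarse-grained molecular networks.

## The model

A network of N sites with energies E_j and undirected couplings V_jk
defines a tight-binding Hamiltonian

    H = Σ_j E_j |s_j⟩⟨s_j| + Σ_{j≠k} V_jk |s_j⟩⟨s_k|

(ħ = 1, dimensionless energies; time in units of 1/|h| for a reference
coupling h). A perturbation localized at the allosteric site at t = 0
evolves as W(t) = exp(−iHt) W(0), with site populations
P_i(t) = |W_i(t)|². Optionally each site couples linearly (and diagonally
in the electronic index) to shared harmonic modes, giving an exciton–bath
(vibronic) Hamiltonian on a truncated product basis.

The first passage of the wave at the active site |a⟩ is summarized by

* **t_a** — arrival time: position of the first qualifying peak of P_a(t),
* **A_a** — amplitude: the height of that peak (1 − A_a is the attenuation),
* **B_a** — broadening: full width of the peak at 2/3 of its height,

together with a least-squares Gaussian fit c1·exp(−(t−c2)²/c3²) over the
window where the peak decays to 1% (a shape diagnostic). For the
degenerate pair these definitions give the closed forms t_a = π/(2|h|),
A_a = 1 and B_a = π(180 − 109.471)/180 ≈ 1.231. The long-time transfer
efficiency is the time-averaged population
⟨P_a⟩ = (1/τ)∫₀^τ P_a(t) dt with τ ≫ t_a.

Beyond constant couplings the package provides

* classical master-equation and general rate-matrix propagation for
  comparison,
* non-Markovian population-coupled chains,
  h_{i,i+1}(t) = (1 + x·P(t))·h (regimes x = ±0.2, ±0.8),
* random environmental modulation of a seeded fraction of the couplings,
* Lanczos tridiagonal reduction from the door-state for large sparse
  Hamiltonians,
* a library of model systems: sequential chains, multi-path networks,
  layered trumpet and double-trumpet systems with their effective-chain
  reductions, and grouped 20-state systems,
* quadratic scaling fits F(N) = a1 + a2·N + a3·N² of t_a, A_a, B_a over
  chains N = 4..15.

## Worked example

Build a 5-site degenerate chain, propagate the wave, and characterize the
active site:

```
$ allowave models sc_chain --N 5 -o chain5.json
$ allowave simulate --network chain5.json --t-end 2000 --points 100000 -o chain5.csv
$ allowave characterize --trajectory chain5.csv --site 5
{
 "site": "5",
 "t_a": 3.3820683843096555,
 "A_a": 0.9423882763607819,
 "B_a": 1.2745973884375732,
 ...
 "tau": 2000.0,
 "converged": true,
 "P_avg_1": 0.2501552876201088,
 "P_avg_2": 0.1667250195632606,
 "P_avg_3": 0.16660353659846314,
 "P_avg_4": 0.1666610882829775,
 "P_avg_5": 0.24985506793519563
}
```

The wave reaches the active site at t_a ≈ 3.38 (natural units; ≈ 1.08 in
units of π, the degenerate-pair period) carrying 94% of the perturbation —
a nearly lossless first passage. The long-time averages show the quantum
steady state: end sites hold ≈ 0.25 each, interior sites ≈ 1/6, i.e. the
active site stays preferentially populated rather than scattering to the
uniform 1/5 = 0.2 a classical walk would give (compare
`allowave classical --N 5 ...`).

The same library is importable directly:

```python
import numpy as np, allowave as aw

net = aw.make_two_path("I", h=1.0, c=1.0)          # the 6-cycle
H = aw.build_tight_binding_hamiltonian(net)
traj = aw.evolve_quantum(H, "1", np.linspace(0, 10, 8001))
sig = aw.first_passage_signature(traj, "4")
print(sig.A_a)                                      # 0.750 (constructive
                                                    # two-path interference)
```

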