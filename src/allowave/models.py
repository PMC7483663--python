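"""Generators for the model systems studied with this package.

All generators are pure functions of their arguments and return validated
:class:`~allowave.network.SiteNetwork` objects with 1-based string site ids.
The perturbation always starts at site "1" (allosteric) and is characterized
at the last site (active).

Available systems:

* ``sc_chain(N, h)`` - N degenerate sequentially coupled sites.
* ``three_path(case, h)`` - a hub site with three branches of couplings
  h, h/sqrt(2), h/sqrt(3); case B extends each branch by one pendant site
  with the same coupling as its branch.
* ``two_path(case, h, c)`` - principal path 1-2-3-4 with coupling h plus a
  second path from 1 to 4 through 2 (I), 3 (II) or 4 (III) extra sites,
  every second-path edge carrying c*h.
* ``trumpet16(h)`` / ``double_trumpet22(h)`` - layered networks that split
  (and, in the double trumpet, re-merge) the wave: layer sizes
  (1,2,4,8,1) and (1,2,4,8,4,2,1).
* ``effective_chain(model, h)`` - the 5- or 7-state degenerate chain whose
  couplings are the layer-to-layer effective couplings of a trumpet.
* ``grouped20(mode, h, ratio)`` - four groups of five degenerate states with
  sequential intra-group coupling h and inter-group coupling ratio*h, either
  through a single bridge state pair or all-to-all between adjacent groups.
"""

from __future__ import annotations

import math

from .network import Coupling, NetworkValidationError, Site, SiteNetwork

__all__ = [
    "make_sc_chain",
    "make_three_path",
    "make_two_path",
    "make_trumpet16",
    "make_double_trumpet22",
    "effective_chain",
    "trumpet_effective_couplings",
    "trumpet_layers",
    "make_grouped20",
    "MODEL_NAMES",
    "make_model",
]


def _degenerate_sites(n: int) -> list[Site]:
    return [Site(str(k), 0.0) for k in range(1, n + 1)]


def make_sc_chain(N: int, h: float = 1.0) -> SiteNetwork:
    """N identical sequentially coupled sites; allosteric = 1, active = N."""
    if N < 2:
        raise NetworkValidationError("N: an SC chain needs at least 2 sites")
    couplings = [Coupling(str(k), str(k + 1), h) for k in range(1, N)]
    return SiteNetwork(_degenerate_sites(N), couplings, "1", str(N))


def make_three_path(case: str, h: float = 1.0) -> SiteNetwork:
    """Hub site 1 with three branches coupled by h, h/sqrt(2), h/sqrt(3).

    Case ``A`` is the bare 4-site hub; case ``B`` appends one pendant site to
    each branch with the branch's own coupling (7 sites in total).
    """
    weights = [h, h / math.sqrt(2.0), h / math.sqrt(3.0)]
    if case == "A":
        couplings = [Coupling("1", str(j + 2), w) for j, w in enumerate(weights)]
        return SiteNetwork(_degenerate_sites(4), couplings, "1", "2")
    if case == "B":
        couplings = [Coupling("1", str(j + 2), w) for j, w in enumerate(weights)]
        couplings += [Coupling(str(j + 2), str(j + 5), w) for j, w in enumerate(weights)]
        return SiteNetwork(_degenerate_sites(7), couplings, "1", "5")
    raise NetworkValidationError(f"case: unknown three-path case {case!r}")


_TWO_PATH_EXTRA = {"I": 2, "II": 3, "III": 4}


def make_two_path(case: str, h: float = 1.0, c: float = 0.5) -> SiteNetwork:
    """Two paths from site 1 to site 4: the principal 1-2-3-4 chain with
    coupling h, and a second path through extra sites with coupling c*h.

    Cases I, II and III put 2, 3 and 4 extra sites on the second path
    (6, 7 and 8 sites in total).  Case I with c = 1 is the 6-cycle.
    """
    if case not in _TWO_PATH_EXTRA:
        raise NetworkValidationError(f"case: unknown two-path case {case!r}")
    if not 0.0 <= c <= 1.0:
        raise NetworkValidationError("c: second-path factor must be in [0, 1]")
    n_extra = _TWO_PATH_EXTRA[case]
    n = 4 + n_extra
    couplings = [Coupling(str(k), str(k + 1), h) for k in range(1, 4)]
    # second-path sites are numbered from the active end: 1 - n - (n-1) - ... - 5 - 4
    second = ["1"] + [str(k) for k in range(n, 4, -1)] + ["4"]
    couplings += [Coupling(a, b, c * h) for a, b in zip(second[:-1], second[1:])]
    return SiteNetwork(_degenerate_sites(n), couplings, "1", "4")


def trumpet_effective_couplings(model: str, h: float = 1.0) -> list[float]:
    """Layer-to-layer effective couplings of the trumpet systems.

    The cascade is h_eff(1,2) = sqrt(h/2), each next value sqrt(previous/2);
    the 16-site trumpet closes with h_eff(4,5) = sqrt(h/8), while the 22-site
    double trumpet mirrors the first three values on its merging half.
    """
    he12 = math.sqrt(h / 2.0)
    he23 = math.sqrt(he12 / 2.0)
    he34 = math.sqrt(he23 / 2.0)
    if model == "trumpet16":
        return [he12, he23, he34, math.sqrt(h / 8.0)]
    if model == "double_trumpet22":
        return [he12, he23, he34, he34, he23, he12]
    raise NetworkValidationError(f"model: unknown trumpet model {model!r}")


_TRUMPET_SIZES = {"trumpet16": (1, 2, 4, 8, 1), "double_trumpet22": (1, 2, 4, 8, 4, 2, 1)}


def trumpet_layers(model: str) -> tuple[tuple[str, ...], ...]:
    """Site ids of each layer of a trumpet system, in generation order."""
    sizes = _TRUMPET_SIZES.get(model)
    if sizes is None:
        raise NetworkValidationError(f"model: unknown trumpet model {model!r}")
    layers, k = [], 1
    for s in sizes:
        layers.append(tuple(str(k + j) for j in range(s)))
        k += s
    return tuple(layers)


def _trumpet(model: str, h: float) -> SiteNetwork:
    if h == 0:
        raise NetworkValidationError("h: trumpet coupling must be nonzero")
    layers = trumpet_layers(model)
    h_eff = trumpet_effective_couplings(model, h)
    couplings: list[Coupling] = []
    for k, he in enumerate(h_eff):
        a, b = layers[k], layers[k + 1]
        if len(b) == 2 * len(a):  # split: each site feeds two children
            edges = [(a[i], b[2 * i + d]) for i in range(len(a)) for d in (0, 1)]
        elif len(a) == 2 * len(b):  # merge: mirror of the split pairing
            edges = [(a[2 * i + d], b[i]) for i in range(len(b)) for d in (0, 1)]
        else:  # funnel into the single active site
            edges = [(x, b[0]) for x in a]
        # uniform per-edge value making the coupling between the layers'
        # symmetric superposition states equal h_eff exactly
        v = he * math.sqrt(len(a) * len(b)) / len(edges)
        couplings += [Coupling(x, y, v) for x, y in edges]
    n = sum(len(l) for l in layers)
    return SiteNetwork(_degenerate_sites(n), couplings, "1", str(n))


def make_trumpet16(h: float = 1.0) -> SiteNetwork:
    """16-site trumpet: successive binary splits 1 -> 2 -> 4 -> 8 -> active."""
    return _trumpet("trumpet16", h)


def make_double_trumpet22(h: float = 1.0) -> SiteNetwork:
    """22-site double trumpet: symmetric split-then-merge over 7 layers."""
    return _trumpet("double_trumpet22", h)


def effective_chain(model: str, h: float = 1.0) -> SiteNetwork:
    """Degenerate chain of layer superposition states of a trumpet system."""
    h_eff = trumpet_effective_couplings(model, h)
    n = len(h_eff) + 1
    couplings = [Coupling(str(k), str(k + 1), he) for k, he in enumerate(h_eff, 1)]
    return SiteNetwork(_degenerate_sites(n), couplings, "1", str(n))


def make_grouped20(mode: str, h: float = 1.0, ratio: float = 0.1) -> SiteNetwork:
    """20 states in four groups of five; sequential intra-group coupling h.

    ``bridge`` couples only the last state of a group to the first state of
    the next group; ``all_to_all`` couples every state of a group to every
    state of the neighboring groups.  Inter-group coupling is ratio*h
    (default 10%).
    """
    if mode not in ("all_to_all", "bridge"):
        raise NetworkValidationError(f"mode: unknown grouped mode {mode!r}")
    if not 0.0 < ratio <= 1.0:
        raise NetworkValidationError("ratio: inter-group ratio must be in (0, 1]")
    couplings = [
        Coupling(str(5 * g + k), str(5 * g + k + 1), h)
        for g in range(4)
        for k in range(1, 5)
    ]
    for g in range(3):
        lo, hi = 5 * g + 1, 5 * (g + 1) + 1
        if mode == "bridge":
            couplings.append(Coupling(str(lo + 4), str(hi), ratio * h))
        else:
            couplings += [
                Coupling(str(lo + a), str(hi + b), ratio * h)
                for a in range(5)
                for b in range(5)
            ]
    return SiteNetwork(_degenerate_sites(20), couplings, "1", "20")


# -- registry used by the command-line interface ------------------------------

MODEL_NAMES = (
    "sc_chain",
    "three_path_A",
    "three_path_B",
    "two_path_I",
    "two_path_II",
    "two_path_III",
    "trumpet16",
    "double_trumpet22",
    "effective_chain_trumpet16",
    "effective_chain_double_trumpet22",
    "grouped20_all_to_all",
    "grouped20_bridge",
)


def make_model(name: str, *, N: int | None = None, h: float = 1.0,
               c: float = 0.5, ratio: float = 0.1) -> SiteNetwork:
    """Build a model system by registry name (see MODEL_NAMES)."""
    if name == "sc_chain":
        if N is None:
            raise NetworkValidationError("N: sc_chain requires a chain length")
        return make_sc_chain(N, h)
    if name.startswith("three_path_"):
        return make_three_path(name.rsplit("_", 1)[1], h)
    if name.startswith("two_path_"):
        return make_two_path(name.rsplit("_", 1)[1], h, c)
    if name == "trumpet16":
        return make_trumpet16(h)
    if name == "double_trumpet22":
        return make_double_trumpet22(h)
    if name.startswith("effective_chain_"):
        return effective_chain(name.removeprefix("effective_chain_"), h)
    if name.startswith("grouped20_"):
        return make_grouped20(name.removeprefix("grouped20_"), h, ratio)
    raise NetworkValidationError(f"model: unknown model name {name!r}")
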