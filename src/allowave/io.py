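"""Reading and writing networks, trajectories and reports.

Network files are UTF-8 JSON:

    {"sites": [{"id": "1", "energy": 0.0}, ...],
     "couplings": [{"i": "1", "j": "2", "h": 1.0}, ...],
     "allosteric": "1", "active": "4",
     "vibronic": {"modes": [{"omega": 1.0, "g": {"1": 0.3}}], "n_max": 4}}

(the "vibronic" block is optional).  Trajectories are CSV with a
``time,P_<id>,...`` header, optionally followed by ``ReW_<id>,ImW_<id>``
columns; reports are flat-key JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .dynamics import Trajectory
from .network import (
    Coupling,
    Mode,
    NetworkValidationError,
    Site,
    SiteNetwork,
    VibronicSpec,
)

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
    "load_vibronic",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_report",
]


def network_to_dict(network: SiteNetwork, vib: VibronicSpec | None = None) -> dict:
    d = {
        "sites": [{"id": s.id, "energy": s.energy} for s in network.sites],
        "couplings": [{"i": c.i, "j": c.j, "h": c.h} for c in network.couplings],
        "allosteric": network.allosteric,
        "active": network.active,
    }
    if vib is not None:
        d["vibronic"] = {
            "modes": [{"omega": m.omega, "g": dict(m.g)} for m in vib.modes],
            "n_max": vib.n_max,
        }
    return d


def _require(d: dict, field: str, context: str = ""):
    if field not in d:
        where = f" in {context}" if context else ""
        raise NetworkValidationError(f"{field}: missing required field{where}")
    return d[field]


def network_from_dict(d: dict) -> SiteNetwork:
    sites_raw = _require(d, "sites")
    couplings_raw = _require(d, "couplings")
    allosteric = _require(d, "allosteric")
    active = _require(d, "active")
    sites = []
    for k, s in enumerate(sites_raw):
        sid = _require(s, "id", f"sites[{k}]")
        sites.append(Site(str(sid), float(s.get("energy", 0.0))))
    couplings = []
    for k, c in enumerate(couplings_raw):
        couplings.append(
            Coupling(
                str(_require(c, "i", f"couplings[{k}]")),
                str(_require(c, "j", f"couplings[{k}]")),
                float(_require(c, "h", f"couplings[{k}]")),
            )
        )
    return SiteNetwork(sites, couplings, str(allosteric), str(active))


def vibronic_from_dict(d: dict) -> VibronicSpec:
    modes_raw = _require(d, "modes", "vibronic")
    n_max = _require(d, "n_max", "vibronic")
    modes = [
        Mode(float(_require(m, "omega", f"vibronic.modes[{k}]")),
             {str(s): float(g) for s, g in m.get("g", {}).items()})
        for k, m in enumerate(modes_raw)
    ]
    return VibronicSpec(modes, int(n_max))


def save_network(
    network: SiteNetwork, path: str | Path, vib: VibronicSpec | None = None
) -> None:
    Path(path).write_text(
        json.dumps(network_to_dict(network, vib), indent=1) + "\n", encoding="utf-8"
    )


def load_network(path: str | Path) -> SiteNetwork:
    try:
        d = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise NetworkValidationError(f"file: invalid JSON ({e})") from e
    return network_from_dict(d)


def load_vibronic(path: str | Path) -> VibronicSpec | None:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    if "vibronic" not in d:
        return None
    return vibronic_from_dict(d["vibronic"])


def _fmt(x: float) -> str:
    return format(x, ".12g")


def write_trajectory_csv(
    traj: Trajectory,
    path: str | Path,
    amplitudes: bool = False,
    time_scale: float = 1.0,
) -> None:
    """Write ``time,P_<id>,...`` rows; optionally ReW/ImW columns.

    ``time_scale`` multiplies the stored (natural-unit) times on output,
    e.g. 1/pi for the degenerate-pair period unit.
    """
    amplitudes = amplitudes and traj.amplitudes is not None
    header = ["time"] + [f"P_{lab}" for lab in traj.labels]
    if amplitudes:
        header += [f"ReW_{lab}" for lab in traj.labels]
        header += [f"ImW_{lab}" for lab in traj.labels]
    with open(path, "w", newline="", encoding="utf-8") as f:
        w = csv.writer(f)
        w.writerow(header)
        for k, t in enumerate(traj.times):
            row = [_fmt(t * time_scale)] + [_fmt(p) for p in traj.populations[k]]
            if amplitudes:
                row += [_fmt(v) for v in traj.amplitudes[k].real]
                row += [_fmt(v) for v in traj.amplitudes[k].imag]
            w.writerow(row)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    with open(path, newline="", encoding="utf-8") as f:
        rows = list(csv.reader(f))
    header, data = rows[0], rows[1:]
    if not header or header[0] != "time":
        raise ValueError("trajectory CSV must start with a 'time' column")
    labels = [h[2:] for h in header if h.startswith("P_")]
    n = len(labels)
    arr = np.array([[float(v) for v in row] for row in data])
    times = arr[:, 0]
    populations = arr[:, 1 : 1 + n]
    amps = None
    if len(header) >= 1 + 3 * n:
        re = arr[:, 1 + n : 1 + 2 * n]
        im = arr[:, 1 + 2 * n : 1 + 3 * n]
        amps = re + 1j * im
    return Trajectory(times, populations, tuple(labels), amplitudes=amps)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=False) + "\n",
                          encoding="utf-8")
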