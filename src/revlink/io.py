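"""File formats: extended XYZ trajectories, topology JSON, crosslink CSV,
and flat TOML configuration files.

All files are plain text and use reduced units.  A trajectory on disk is a
triple of files sharing a stem:

* ``<stem>.xyz``      -- extended XYZ; per monomer: species label (A/B),
  chain id, crosslinkable flag, wrapped x/y/z, image ix/iy/iz;
* ``<stem>.bonds.csv``-- per-frame crosslink registry: frame, a_id, b_id;
* ``<stem>.json``     -- topology (chain architecture, counts, box).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from revlink.model import ModelParameters, SystemTopology
from revlink.simulate import Trajectory, TrajectoryFrame

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_topology",
    "read_topology",
    "load_config",
    "save_config",
]

def write_topology(topology: SystemTopology, path) -> None:
    data = {
        "NA": topology.NA, "NB": topology.NB,
        "a_positions": list(topology.a_positions),
        "b_pattern": list(topology.b_pattern),
        "nA": topology.nA, "nB": topology.nB,
        "box": list(topology.box),
    }
    Path(path).write_text(json.dumps(data, indent=1))


def read_topology(path) -> SystemTopology:
    data = json.loads(Path(path).read_text())
    return SystemTopology(
        NA=data["NA"], NB=data["NB"],
        a_positions=tuple(data["a_positions"]),
        b_pattern=tuple(data["b_pattern"]),
        nA=data["nA"], nB=data["nB"], box=tuple(data["box"]),
    )


def write_trajectory(trajectory: Trajectory, stem) -> None:
    """Write a trajectory as ``<stem>.xyz`` + ``<stem>.bonds.csv`` +
    ``<stem>.json``.  Float coordinates are written with repr-round-trip
    precision so re-reading reproduces them bit-exactly."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    topo = trajectory.topology
    write_topology(topo, stem.with_suffix(".json"))
    from revlink.simulate import build_system
    layout = build_system(topo)
    labels = np.where(layout.species == 0, "A", "B")
    with open(stem.with_suffix(".xyz"), "w") as fx, \
            open(stem.parent / (stem.name + ".bonds.csv"), "w") as fb:
        fb.write("frame,a_id,b_id\n")
        for fi, fr in enumerate(trajectory.frames):
            n = len(fr.positions)
            fx.write(f"{n}\n")
            Lx, Ly, Lz = fr.box
            fx.write(
                f'Lattice="{Lx:.17g} 0 0 0 {Ly:.17g} 0 0 0 {Lz:.17g}" '
                f'Properties=species:S:1:chain:I:1:crosslinkable:I:1:'
                f'pos:R:3:image:I:3 Time={fr.time:.17g}\n')
            for i in range(n):
                x, y, z = fr.positions[i]
                ix, iy, iz = fr.images[i]
                fx.write(f"{labels[i]} {layout.chain_id[i]} "
                         f"{int(layout.link_type[i] > 0)} "
                         f"{x:.17g} {y:.17g} {z:.17g} {ix} {iy} {iz}\n")
            for a, b in sorted(fr.pairs):
                fb.write(f"{fi},{a},{b}\n")


def read_trajectory(stem, params: ModelParameters | None = None) -> Trajectory:
    stem = Path(stem)
    topo = read_topology(stem.with_suffix(".json"))
    pairs_by_frame: dict[int, set] = {}
    bonds_file = stem.parent / (stem.name + ".bonds.csv")
    if bonds_file.exists():
        with open(bonds_file) as fb:
            next(fb)
            for line in fb:
                fi, a, b = (int(v) for v in line.split(","))
                pairs_by_frame.setdefault(fi, set()).add((a, b))
    frames = []
    with open(stem.with_suffix(".xyz")) as fx:
        fi = 0
        while True:
            head = fx.readline()
            if not head:
                break
            n = int(head)
            comment = fx.readline()
            lat = comment.split('Lattice="')[1].split('"')[0].split()
            box = (float(lat[0]), float(lat[4]), float(lat[8]))
            time = float(comment.rsplit("Time=", 1)[1].split()[0])
            pos = np.empty((n, 3))
            img = np.empty((n, 3), dtype=np.int64)
            for i in range(n):
                parts = fx.readline().split()
                pos[i] = [float(v) for v in parts[3:6]]
                img[i] = [int(v) for v in parts[6:9]]
            frames.append(TrajectoryFrame(
                time=time, positions=pos, images=img, box=box,
                pairs=frozenset(pairs_by_frame.get(fi, set()))))
            fi += 1
    return Trajectory(topology=topo, params=params or ModelParameters(),
                      frames=frames)


# ---------------------------------------------------------------------------
# flat TOML configuration
# ---------------------------------------------------------------------------

_PARAM_KEYS = {f: getattr(ModelParameters(), f)
               for f in ModelParameters.__dataclass_fields__}
_TOPO_KEYS = ("NA", "NB", "a_positions", "b_pattern", "nA", "nB", "box")


def save_config(params: ModelParameters, topology: SystemTopology, path) -> None:
    lines = ["# revlink run configuration (reduced units)"]
    for k in ModelParameters.__dataclass_fields__:
        lines.append(f"{k} = {getattr(params, k)!r}")
    lines.append(f"NA = {topology.NA}")
    lines.append(f"NB = {topology.NB}")
    lines.append(f"a_positions = {list(topology.a_positions)}")
    lines.append(f"b_pattern = {list(topology.b_pattern)}")
    lines.append(f"nA = {topology.nA}")
    lines.append(f"nB = {topology.nB}")
    lines.append(f"box = {list(topology.box)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> tuple[ModelParameters, SystemTopology]:
    """Load a flat TOML config; unknown keys are rejected with a list of
    valid ones, missing topology keys raise a descriptive error."""
    import tomllib

    text = Path(path).read_text()
    data = tomllib.loads(text)
    unknown = set(data) - set(_PARAM_KEYS) - set(_TOPO_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                         f"valid keys: {sorted(set(_PARAM_KEYS) | set(_TOPO_KEYS))}")
    missing = [k for k in _TOPO_KEYS if k not in data]
    if missing:
        raise ValueError(f"missing required topology keys: {missing}")
    pkw = {k: data[k] for k in _PARAM_KEYS if k in data}
    params = ModelParameters(**pkw)
    topo = SystemTopology(
        NA=int(data["NA"]), NB=int(data["NB"]),
        a_positions=tuple(data["a_positions"]),
        b_pattern=tuple(data["b_pattern"]),
        nA=int(data["nA"]), nB=int(data["nB"]),
        box=tuple(float(v) for v in data["box"]),
    )
    return params, topo
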