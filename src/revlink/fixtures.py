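"""Deterministic synthetic configurations exercising the analysis operators.

Each fixture is reproducible from its name, parameters and seed.  They are
used by the test suite and available from the CLI for quick sanity checks:

* ``winding-chain``: a bonded chain winding once around the periodic box
  (percolating by construction);
* ``dimer``: one registered A-B crosslink pair (non-spanning);
* ``ideal-gas``: uniformly random points (flat profile, S(k) = 1, g(r) = 1);
* ``sc-lattice``: simple cubic lattice (Bragg peak at 2 pi / a);
* ``tanh-slab``: frames Poisson-sampled from a two-plateau slab density
  (known coexistence densities and interface width).
"""

from __future__ import annotations

import numpy as np

from revlink.model import SystemTopology
from revlink.simulate import Trajectory, TrajectoryFrame

__all__ = ["generate_fixture", "FIXTURES"]


def _chain_topology(n_monomers: int, box) -> SystemTopology:
    """A single neutral B-chain spanning all monomers."""
    return SystemTopology(NA=1, NB=n_monomers, a_positions=(0,),
                          b_pattern=(0,) * n_monomers, nA=0, nB=1, box=box)


def _points_topology(n: int, box) -> SystemTopology:
    """n independent single-monomer neutral chains."""
    return SystemTopology(NA=1, NB=1, a_positions=(0,), b_pattern=(0,),
                          nA=0, nB=n, box=box)


def winding_chain(L: float = 10.0, spacing: float = 1.0) -> tuple[Trajectory, SystemTopology]:
    """Straight bonded chain along x closed into a ring through the periodic
    boundary by a synthetic crosslink between its ends.

    The closure edge carries a net image displacement along x, so the cycle
    connects every monomer to its own periodic image: the cluster spans x.
    (A *linear* chain never percolates under the strict image criterion --
    winding requires a cycle.)
    """
    n = int(round(L / spacing))
    box = (L, L, L)
    topo = _chain_topology(n, box)
    pos = np.zeros((n, 3))
    pos[:, 0] = (np.arange(n) * spacing) % L
    pos[:, 1] = L / 2
    pos[:, 2] = L / 2
    frame = TrajectoryFrame(time=0.0, positions=pos,
                            images=np.zeros((n, 3), dtype=np.int64),
                            box=box, pairs=frozenset({(0, n - 1)}))
    return Trajectory(topology=topo, params=None, frames=[frame]), topo


def dimer(L: float = 10.0, r: float = 0.3) -> tuple[Trajectory, SystemTopology]:
    """One A-monomer bound to one B-monomer at separation r."""
    box = (L, L, L)
    topo = SystemTopology(NA=1, NB=1, a_positions=(0,), b_pattern=(1,),
                          nA=1, nB=1, box=box)
    pos = np.array([[L / 2, L / 2, L / 2], [L / 2 + r, L / 2, L / 2]])
    frame = TrajectoryFrame(time=0.0, positions=pos,
                            images=np.zeros((2, 3), dtype=np.int64),
                            box=box, pairs=frozenset({(0, 1)}))
    return Trajectory(topology=topo, params=None, frames=[frame]), topo


def ideal_gas(n: int, L: float, seed: int, n_frames: int = 1) -> tuple[Trajectory, SystemTopology]:
    rng = np.random.default_rng(seed)
    box = (L, L, L)
    topo = _points_topology(n, box)
    frames = []
    for k in range(n_frames):
        pos = rng.random((n, 3)) * L
        frames.append(TrajectoryFrame(
            time=float(k), positions=pos,
            images=np.zeros((n, 3), dtype=np.int64),
            box=box, pairs=frozenset()))
    return Trajectory(topology=topo, params=None, frames=frames), topo


def sc_lattice(cells: int = 5, a: float = 2.0) -> tuple[Trajectory, SystemTopology]:
    L = cells * a
    box = (L, L, L)
    g = np.arange(cells) * a
    pos = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
    topo = _points_topology(len(pos), box)
    frame = TrajectoryFrame(time=0.0, positions=pos.astype(float),
                            images=np.zeros((len(pos), 3), dtype=np.int64),
                            box=box, pairs=frozenset())
    return Trajectory(topology=topo, params=None, frames=[frame]), topo


def tanh_slab(
    dense: float = 0.04,
    dilute: float = 0.002,
    width: float = 2.0,
    box=(10.0, 60.0, 10.0),
    n_frames: int = 20,
    seed: int = 0,
    a_fraction: float = 0.5,
) -> tuple[Trajectory, SystemTopology]:
    """Frames Poisson-sampled from a two-interface tanh density profile
    along y (slab occupying the central third), split between an A and a B
    point species with fixed fraction."""
    rng = np.random.default_rng(seed)
    Lx, Ly, Lz = box
    y1, y2 = Ly / 3.0, 2.0 * Ly / 3.0

    def rho(y):
        return dilute + 0.5 * (dense - dilute) * (
            np.tanh((y - y1) / width) - np.tanh((y - y2) / width))

    ygrid = np.linspace(0, Ly, 2000)
    rho_max = rho(ygrid).max()
    n = int(round(float(np.trapezoid(rho(ygrid), ygrid) * Lx * Lz)))
    frames = []
    for k in range(n_frames):
        ys = []
        while len(ys) < n:  # rejection sampling from the profile
            cand = rng.random(4 * n) * Ly
            acc = cand[rng.random(4 * n) < rho(cand) / rho_max]
            ys.extend(acc.tolist())
        ys = np.asarray(ys[:n])
        pos = np.column_stack([rng.random(n) * Lx, ys, rng.random(n) * Lz])
        frames.append(TrajectoryFrame(
            time=float(k), positions=pos,
            images=np.zeros((n, 3), dtype=np.int64),
            box=box, pairs=frozenset()))
    nA = int(round(a_fraction * n))
    topo = SystemTopology(NA=1, NB=1, a_positions=(0,), b_pattern=(0,),
                          nA=nA, nB=n - nA, box=box)
    return Trajectory(topology=topo, params=None, frames=frames), topo


FIXTURES = {
    "winding-chain": winding_chain,
    "dimer": dimer,
    "ideal-gas": ideal_gas,
    "sc-lattice": sc_lattice,
    "tanh-slab": tanh_slab,
}


def generate_fixture(name: str, **kwargs):
    """Build a named fixture; raises KeyError listing known names."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    return FIXTURES[name](**kwargs)
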