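"""Langevin-dynamics engine with a dynamic one-to-one crosslink registry.

The engine integrates bead-spring A/B chains whose crosslinkable monomers
form saturating reversible bonds.  Two protocols are provided:

* :func:`run_bulk_simulation` -- production run in a fixed (typically cubic)
  periodic box, used for percolation thresholds and single-chain statistics;
* :func:`run_slab_protocol` -- the slab workflow for coexistence densities:
  a pre-run in a cubic box, extension of one axis (unwrapping chains across
  the seam), equilibration, and a production run emitting a fixed number of
  frames.

Positions are stored wrapped together with integer image counters, so
unwrapped coordinates ``wrapped + image * L`` trace continuous paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from revlink import _kernel
from revlink.model import ModelParameters, SystemTopology

__all__ = [
    "BindingRegistry",
    "TrajectoryFrame",
    "Trajectory",
    "SlabProtocolSpec",
    "SystemState",
    "build_system",
    "initialize_positions",
    "compute_forces",
    "update_bindings",
    "run_bulk_simulation",
    "run_slab_protocol",
]


class BindingRegistry:
    """One-to-one registry of crosslink pairs (a_monomer, b_monomer)."""

    def __init__(self, pairs=()):
        self._partner: dict[int, int] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: int, b: int) -> None:
        if a in self._partner or b in self._partner:
            raise ValueError(f"monomer already bound: pair ({a}, {b})")
        self._partner[a] = b
        self._partner[b] = a

    def remove(self, a: int, b: int) -> None:
        if self._partner.get(a) != b:
            raise KeyError(f"pair ({a}, {b}) not registered")
        del self._partner[a]
        del self._partner[b]

    def partner_of(self, i: int) -> int | None:
        return self._partner.get(i)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return {(a, b) for a, b in self._partner.items() if a < b}

    def __len__(self) -> int:
        return len(self._partner) // 2

    def to_array(self, n: int) -> np.ndarray:
        arr = np.full(n, -1, dtype=np.int64)
        for i, j in self._partner.items():
            arr[i] = j
        return arr

    @classmethod
    def from_array(cls, partner: np.ndarray) -> "BindingRegistry":
        reg = cls()
        for i, j in enumerate(partner):
            if j >= 0 and i < j:
                reg.add(int(i), int(j))
        return reg

    def validate(self, link_type: np.ndarray, positions=None, box=None,
                 r_bind: float = 0.5) -> None:
        """Audit the one-to-one invariants (and separations if given)."""
        for i, j in self._partner.items():
            if self._partner[j] != i:
                raise AssertionError("registry reverse index inconsistent")
            if {int(link_type[i]), int(link_type[j])} != {1, 2}:
                raise AssertionError("registered pair is not an A/B crosslinker pair")
        if positions is not None and box is not None:
            box = np.asarray(box)
            for a, b in self.pairs:
                d = positions[a] - positions[b]
                d -= box * np.rint(d / box)
                if np.linalg.norm(d) >= r_bind:
                    raise AssertionError("registered pair beyond binding cutoff")


@dataclass
class TrajectoryFrame:
    """One saved configuration: wrapped positions, images, box, registry."""

    time: float
    positions: np.ndarray          # (N, 3), wrapped
    images: np.ndarray             # (N, 3), int
    box: tuple[float, float, float]
    pairs: frozenset               # frozenset of (a, b) crosslink pairs, a < b
    kinetic_energy: float = np.nan
    potential_energy: float = np.nan

    @property
    def unwrapped(self) -> np.ndarray:
        return self.positions + self.images * np.asarray(self.box)

    def partner_array(self) -> np.ndarray:
        arr = np.full(len(self.positions), -1, dtype=np.int64)
        for a, b in self.pairs:
            arr[a] = b
            arr[b] = a
        return arr


@dataclass
class Trajectory:
    """Frames plus the static description of the system that produced them."""

    topology: SystemTopology
    params: ModelParameters
    frames: list[TrajectoryFrame] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SlabProtocolSpec:
    """Durations and geometry of the slab coexistence protocol [t0, sigma].

    The defaults are the full-scale protocol: 30^3 initial cube, extension of
    the y-axis to 300 sigma, 5e4 t0 pre-run, 5e5 t0 equilibration and
    production, 100 production frames.
    """

    initial_box: float = 30.0
    extension_axis: int = 1
    final_length: float = 300.0
    pre_run: float = 5.0e4
    equilibration: float = 5.0e5
    production: float = 5.0e5
    n_frames: int = 100

    def __post_init__(self) -> None:
        if min(self.pre_run, self.equilibration, self.production) <= 0:
            raise ValueError("durations must be positive")
        if self.final_length < self.initial_box:
            raise ValueError("extension must enlarge the box")
        if self.extension_axis not in (0, 1, 2):
            raise ValueError("extension_axis must be 0, 1 or 2")
        if self.n_frames < 1:
            raise ValueError("need at least one production frame")

    @classmethod
    def reduced(cls, initial_box: float = 20.0, factor: float = 5.0,
                pre_run: float = 500.0, equilibration: float = 1.0e4,
                production: float = 5.0e3, n_frames: int = 100) -> "SlabProtocolSpec":
        """Scaled-down protocol for desk-scale qualitative checks."""
        return cls(initial_box=initial_box, final_length=initial_box * factor,
                   pre_run=pre_run, equilibration=equilibration,
                   production=production, n_frames=n_frames)


@dataclass
class SystemState:
    """Flat per-monomer arrays consumed by the compiled kernel."""

    positions: np.ndarray   # (N, 3) wrapped
    images: np.ndarray      # (N, 3) int64
    velocities: np.ndarray  # (N, 3)
    box: np.ndarray         # (3,)
    bonds: np.ndarray       # (nb, 2) int64
    angles: np.ndarray      # (na, 3) int64
    link_type: np.ndarray   # (N,) int8: 0 neutral / 1 A-crosslinker / 2 B-crosslinker
    chain_id: np.ndarray    # (N,) int64
    species: np.ndarray     # (N,) int8: 0 = A-chain monomer, 1 = B-chain monomer
    partner: np.ndarray     # (N,) int64, -1 = free


def build_system(topology: SystemTopology) -> SystemState:
    """Allocate per-monomer arrays for a topology (positions unset).

    Monomers are numbered consecutively within each chain, A-chains first.
    """
    n = topology.n_monomers
    link_type = np.zeros(n, dtype=np.int8)
    chain_id = np.zeros(n, dtype=np.int64)
    species = np.zeros(n, dtype=np.int8)
    bonds = []
    angles = []
    idx = 0
    cid = 0
    for _ in range(topology.nA):
        start = idx
        for k in range(topology.NA):
            chain_id[idx] = cid
            if k in topology.a_positions:
                link_type[idx] = 1
            idx += 1
        bonds.extend((start + k, start + k + 1) for k in range(topology.NA - 1))
        angles.extend((start + k, start + k + 1, start + k + 2)
                      for k in range(topology.NA - 2))
        cid += 1
    for _ in range(topology.nB):
        start = idx
        for k in range(topology.NB):
            chain_id[idx] = cid
            species[idx] = 1
            if topology.b_pattern[k] == 1:
                link_type[idx] = 2
            idx += 1
        bonds.extend((start + k, start + k + 1) for k in range(topology.NB - 1))
        angles.extend((start + k, start + k + 1, start + k + 2)
                      for k in range(topology.NB - 2))
        cid += 1
    return SystemState(
        positions=np.zeros((n, 3)),
        images=np.zeros((n, 3), dtype=np.int64),
        velocities=np.zeros((n, 3)),
        box=np.asarray(topology.box, dtype=float),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        link_type=link_type,
        chain_id=chain_id,
        species=species,
        partner=np.full(n, -1, dtype=np.int64),
    )


def initialize_positions(state: SystemState, topology: SystemTopology,
                         rng: np.random.Generator, r0: float,
                         min_dist: float = 0.9,
                         max_attempts: int = 100_000) -> None:
    """Random non-overlapping initialisation by sequential chain growth.

    Each chain grows monomer by monomer at bond length ``r0`` in random
    directions; a placement closer than ``min_dist`` to any existing monomer
    is rejected.  In dense boxes the criterion is relaxed stepwise down to
    0.8 sigma (residual soft overlaps relax within a few steps under the
    capped forces); raises after ``max_attempts`` failed placements at the
    loosest criterion (suggesting a larger box).
    """
    box = state.box
    n = len(state.positions)
    if n == 0:
        return
    chain_lengths = [topology.NA] * topology.nA + [topology.NB] * topology.nB
    arr = np.empty((n, 3))

    def grow(md: float, budget: int) -> bool:
        md2 = md * md
        count = 0
        attempts = 0

        def clear(cand: np.ndarray, upto: int) -> bool:
            if upto == 0:
                return True
            d = cand - arr[:upto]
            d -= box * np.rint(d / box)
            return bool(np.min((d * d).sum(axis=1)) >= md2)

        for length in chain_lengths:
            while True:
                k0 = count
                arr[k0] = rng.random(3) * box
                placed_in_chain = 1
                ok = clear(arr[k0], k0)
                while ok and placed_in_chain < length:
                    i = k0 + placed_in_chain
                    for _ in range(30):
                        u = rng.normal(size=3)
                        u /= np.linalg.norm(u)
                        cand = arr[i - 1] + r0 * u
                        if clear(cand, i):
                            arr[i] = cand
                            placed_in_chain += 1
                            break
                    else:
                        ok = False
                attempts += 1
                if ok:
                    count = k0 + length
                    break
                if attempts > budget:
                    return False
        return True

    levels = [md for md in (min_dist, 0.85, 0.8) if md <= min_dist]
    for k, md in enumerate(levels):
        # fail fast on the stricter criteria; spend the full budget only on
        # the loosest one
        budget = max_attempts if k == len(levels) - 1 \
            else max(100, 10 * len(chain_lengths))
        if grow(md, budget):
            break
    else:
        raise RuntimeError(
            "could not place chains without overlap; use a larger box"
        )
    # keep the true image shifts so unwrapped coordinates reproduce the
    # continuous growth path (chains stay contiguous across the boundary)
    shift = np.floor(arr / box)
    state.positions[:] = arr - shift * box
    state.images[:] = shift.astype(np.int64)


def _draw_velocities(state: SystemState, params: ModelParameters,
                     rng: np.random.Generator) -> None:
    n = len(state.positions)
    state.velocities[:] = rng.normal(
        scale=np.sqrt(params.kBT / params.mass), size=(n, 3))


def compute_forces(state: SystemState, params: ModelParameters,
                   wca_bonded: bool = False) -> tuple[np.ndarray, float]:
    """Forces on every monomer [kBT/sigma] and total potential energy [kBT]."""
    return _kernel.compute_forces_energy(
        state.positions, state.box, state.bonds, state.angles,
        state.link_type, state.chain_id, state.partner,
        params.kb, params.r0, params.ka, params.eps_wca, params.eps_sp,
        1 if wca_bonded else 0)


def update_bindings(state: SystemState, params: ModelParameters) -> int:
    """One registry update on the current positions; returns pairs formed."""
    return _kernel.update_bindings(
        state.positions, state.box, state.link_type, state.partner,
        params.r_bind)


def _segment(state: SystemState, params: ModelParameters, n_steps: int,
             save_every: int, seed: int, wca_bonded: bool = False,
             t_offset: float = 0.0) -> list[TrajectoryFrame]:
    """Run one kernel segment in place; return any saved frames.

    The segment is driven in chunks: Langevin noise is pre-generated per
    chunk with numpy's PCG64 generator (seeded once per segment, hence
    deterministic) and consumed by the compiled integrator.
    """
    n = len(state.positions)
    if n == 0 or n_steps <= 0:
        return []
    rng = np.random.default_rng(seed % (2 ** 31))
    nsave = n_steps // save_every if save_every > 0 else 0
    tp = np.empty((nsave, n, 3))
    ti = np.empty((nsave, n, 3), dtype=np.int64)
    tpart = np.empty((nsave, n), dtype=np.int64)
    tt = np.empty(nsave)
    tke = np.empty(nsave)
    tpe = np.empty(nsave)
    nlist = np.empty((n, _kernel.MAX_NEIGH), dtype=np.int64)
    ncount = np.zeros(n, dtype=np.int64)
    ref_pos = np.empty((n, 3))
    forces = np.zeros((n, 3))
    rebuild = np.ones(1, dtype=np.int64)

    chunk = min(20000, max(200, int(6e6 / max(3 * n, 1))))
    isave = 0
    step0 = 0
    while step0 < n_steps:
        this = min(chunk, n_steps - step0)
        if params.gamma > 0:
            stride = _kernel.NOISE_STRIDE
            n_kicks = (step0 + this) // stride - step0 // stride
            noise = rng.standard_normal((max(n_kicks, 1), 3 * n))
        else:
            noise = np.zeros((1, 3 * n))
        isave, status = _kernel.run_chunk(
            state.positions, state.images, state.velocities, state.box,
            state.bonds, state.angles, state.link_type, state.chain_id,
            state.partner, params.kb, params.r0, params.ka, params.eps_wca,
            params.eps_sp, params.r_bind, 1 if wca_bonded else 0,
            params.dt, params.gamma, params.mass, params.kBT,
            step0, this, save_every, noise,
            nlist, ncount, ref_pos, forces, rebuild,
            tp, ti, tpart, tt, tke, tpe, isave)
        if status == _kernel.STATUS_NONFINITE:
            raise RuntimeError("integration diverged: non-finite coordinates")
        if status == _kernel.STATUS_BLOWUP:
            raise RuntimeError(
                "integration unstable: single-step displacement exceeded "
                "half the box"
            )
        if status == _kernel.STATUS_NLIST_OVERFLOW:
            raise RuntimeError("neighbour list overflow: system too dense")
        step0 += this
    frames = []
    box = tuple(float(L) for L in state.box)
    for k in range(isave):
        part = tpart[k]
        pairs = frozenset(
            (int(i), int(part[i])) for i in np.flatnonzero(part >= 0)
            if i < part[i]
        )
        frames.append(TrajectoryFrame(
            time=t_offset + float(tt[k]),
            positions=tp[k].copy(), images=ti[k].copy(), box=box,
            pairs=pairs, kinetic_energy=float(tke[k]),
            potential_energy=float(tpe[k])))
    return frames


def _steps(duration: float, dt: float) -> int:
    return max(1, int(round(duration / dt)))


def run_bulk_simulation(
    params: ModelParameters,
    topology: SystemTopology,
    duration: float,
    seed: int,
    frame_interval: float | None = None,
    equilibration: float = 0.0,
    wca_bonded: bool = False,
    state: SystemState | None = None,
) -> Trajectory:
    """Bulk run in the topology's periodic box.

    ``duration`` and ``frame_interval`` are in t0; frames are saved every
    ``frame_interval`` (default: 100 frames over the run).  An optional
    ``equilibration`` period runs first without saving frames.  A pre-built
    ``state`` (e.g. from a previous run) bypasses random initialisation.
    """
    traj = Trajectory(topology=topology, params=params)
    if topology.n_monomers == 0:
        return traj
    rng = np.random.default_rng(seed)
    if state is None:
        state = build_system(topology)
        initialize_positions(state, topology, rng, params.r0)
        _draw_velocities(state, params, rng)
    if frame_interval is None:
        frame_interval = duration / 100.0
    save_every = max(1, int(round(frame_interval / params.dt)))
    if equilibration > 0:
        _segment(state, params, _steps(equilibration, params.dt), 0,
                 int(rng.integers(2 ** 31)), wca_bonded)
    n_steps = _steps(duration, params.dt)
    traj.frames = _segment(state, params, n_steps, save_every,
                           int(rng.integers(2 ** 31)), wca_bonded,
                           t_offset=equilibration)
    return traj


def run_slab_protocol(
    spec: SlabProtocolSpec,
    params: ModelParameters,
    topology: SystemTopology,
    seed: int,
    wca_bonded: bool = False,
) -> Trajectory:
    """Slab coexistence protocol: cubic pre-run, extension, equilibration,
    production.

    ``topology.box`` must be the cubic initial box (all sides equal to
    ``spec.initial_box``); the returned trajectory carries the extended box.
    The extension keeps all coordinates (vacuum is appended), so particle
    count and intra-chain bond lengths are conserved at the extension
    instant; chains are re-unwrapped along the extension axis so that no
    chain is cut by the seam.
    """
    L0 = spec.initial_box
    if any(abs(L - L0) > 1e-9 for L in topology.box):
        raise ValueError("topology box must equal the cubic initial box of the spec")
    rng = np.random.default_rng(seed)
    state = build_system(topology)
    initialize_positions(state, topology, rng, params.r0)
    _draw_velocities(state, params, rng)

    # 1. pre-run in the cubic box
    _segment(state, params, _steps(spec.pre_run, params.dt), 0,
             int(rng.integers(2 ** 31)), wca_bonded)

    # 2. extend the box; unwrap chains along the extension axis first so
    # that chains crossing the seam stay contiguous, then recentre
    ax = spec.extension_axis
    # image counters kept during the pre-run make unwrapped coordinates
    # continuous within each chain, so chains crossing the seam stay whole
    unwrapped = state.positions + state.images * state.box
    for cid in np.unique(state.chain_id):
        coords = unwrapped[state.chain_id == cid, ax]
        if coords.max() - coords.min() > 0.5 * L0:
            warnings.warn("chain spans more than half the short box at "
                          "extension time; unwrap may be ambiguous")
    new_box = state.box.copy()
    new_box[ax] = spec.final_length
    # place the old box centre at the centre of the new box
    unwrapped[:, ax] += 0.5 * (spec.final_length - L0)
    state.images = np.floor(unwrapped / new_box).astype(np.int64)
    state.positions = unwrapped - state.images * new_box
    state.box = new_box

    # 3. equilibration
    _segment(state, params, _steps(spec.equilibration, params.dt), 0,
             int(rng.integers(2 ** 31)), wca_bonded)

    # 4. production: exactly n_frames frames
    n_steps_frame = max(1, int(round(spec.production / spec.n_frames / params.dt)))
    n_steps = n_steps_frame * spec.n_frames
    topo_ext = SystemTopology(
        NA=topology.NA, NB=topology.NB, a_positions=topology.a_positions,
        b_pattern=topology.b_pattern, nA=topology.nA, nB=topology.nB,
        box=tuple(float(L) for L in new_box))
    traj = Trajectory(topology=topo_ext, params=params)
    traj.frames = _segment(state, params, n_steps, n_steps_frame,
                           int(rng.integers(2 ** 31)), wca_bonded)
    return traj
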