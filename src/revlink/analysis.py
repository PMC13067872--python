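"""Trajectory-derived observables.

Covers the full observable set of the model study:

* slab density profiles and coexistence densities (tanh interface fits and
  block-distribution analysis);
* cluster and percolation analysis under periodic boundaries, where a
  cluster percolates when a continuous bond path links a monomer to one of
  its own periodic images (detected through union-find with per-edge image
  offset vectors);
* binding-motif classification of A-chains (unbound / singly bound / loop /
  bridge);
* static structure factors and radial distribution functions;
* single-chain statistics: radius of gyration, persistence length,
  end-to-end decorrelation time and the overlap concentration
  c* = N / ((4/3) pi Rg^3).

All operators consume :class:`revlink.simulate.TrajectoryFrame` /
:class:`~revlink.simulate.Trajectory` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from revlink.model import SystemTopology
from revlink.simulate import Trajectory, TrajectoryFrame

__all__ = [
    "DensityProfile",
    "PercolationResult",
    "MotifStats",
    "PhasePointEstimate",
    "ChainStatistics",
    "density_profile",
    "coexistence_from_profile",
    "block_distribution_coexistence",
    "connectivity_and_percolation",
    "percolation_threshold_map",
    "classify_motifs",
    "structure_factor",
    "rdf",
    "chain_statistics",
    "monomer_chain_map",
]


# ---------------------------------------------------------------------------
# cluster / percolation machinery
# ---------------------------------------------------------------------------

class _OffsetUnionFind:
    """Union-find where each node carries an integer image offset relative to
    its parent; merging an edge that closes a cycle with a nonzero net offset
    reveals a path from a particle to one of its periodic images (winding)."""

    def __init__(self, n: int):
        self.parent = np.arange(n)
        self.offset = np.zeros((n, 3), dtype=np.int64)
        self.winding = {}  # root -> bool[3]

    def find(self, i: int) -> tuple[int, np.ndarray]:
        path = []
        while self.parent[i] != i:
            path.append(i)
            i = self.parent[i]
        # path compression with offset accumulation (leaf-to-root order)
        total = np.zeros(3, dtype=np.int64)
        for j in reversed(path):
            total = total + self.offset[j]
            self.parent[j] = i
            self.offset[j] = total.copy()
        return i, (self.offset[path[0]].copy() if path else np.zeros(3, dtype=np.int64))

    def union(self, i: int, j: int, shift: np.ndarray) -> None:
        """Join i and j where ``shift`` is the image offset of the edge:
        the bonded copy of j sits at pos_j + shift * box relative to i."""
        ri, oi = self.find(i)
        rj, oj = self.find(j)
        if ri == rj:
            mismatch = oi - (oj + shift)
            if np.any(mismatch != 0):
                w = self.winding.setdefault(ri, np.zeros(3, dtype=bool))
                w |= mismatch != 0
            return
        # attach rj under ri: offset of rj = oi - shift - oj
        self.parent[rj] = ri
        self.offset[rj] = oi - shift - oj
        if rj in self.winding:
            w = self.winding.setdefault(ri, np.zeros(3, dtype=bool))
            w |= self.winding.pop(rj)


@dataclass
class PercolationResult:
    """Cluster labels per chain and spanning flags of the bond network."""

    chain_labels: np.ndarray          # cluster id per chain
    spans_axis: np.ndarray            # bool[3], any cluster spanning axis k
    spanning: bool                    # any axis
    largest_cluster: int              # size in chains
    second_largest_cluster: int       # size in chains
    monomer_labels: np.ndarray = field(repr=False, default=None)


def monomer_chain_map(topology: SystemTopology) -> np.ndarray:
    """chain id for every monomer (A-chains first, consecutive numbering)."""
    ids = np.empty(topology.n_monomers, dtype=np.int64)
    k = 0
    cid = 0
    for _ in range(topology.nA):
        ids[k:k + topology.NA] = cid
        k += topology.NA
        cid += 1
    for _ in range(topology.nB):
        ids[k:k + topology.NB] = cid
        k += topology.NB
        cid += 1
    return ids


def _bond_edges(topology: SystemTopology) -> np.ndarray:
    edges = []
    k = 0
    for _ in range(topology.nA):
        edges.extend((k + i, k + i + 1) for i in range(topology.NA - 1))
        k += topology.NA
    for _ in range(topology.nB):
        edges.extend((k + i, k + i + 1) for i in range(topology.NB - 1))
        k += topology.NB
    return np.asarray(edges, dtype=np.int64).reshape(-1, 2)


def connectivity_and_percolation(
    frame: TrajectoryFrame, topology: SystemTopology
) -> PercolationResult:
    """Bond-network clusters and periodic-image spanning flags.

    Graph nodes are monomers; edges are backbone bonds plus registered
    crosslinks.  Each edge carries the integer image offset of the
    minimum-image displacement; a cluster spans axis k when an edge closing
    a cycle carries a net nonzero offset along k.  Chain-level clusters are
    obtained by contracting backbones (every monomer of a chain shares its
    cluster by construction).
    """
    n = len(frame.positions)
    if n != topology.n_monomers:
        raise ValueError("frame size does not match topology")
    box = np.asarray(frame.box)
    edges = _bond_edges(topology)
    cross = np.asarray(sorted(frame.pairs), dtype=np.int64).reshape(-1, 2)
    all_edges = np.vstack([edges, cross]) if len(cross) else edges
    uf = _OffsetUnionFind(n)
    pos = frame.positions
    for i, j in all_edges:
        d = pos[i] - pos[j]
        shift = -np.rint(d / box).astype(np.int64)  # bonded image of j
        uf.union(int(i), int(j), shift)
    roots = np.empty(n, dtype=np.int64)
    for i in range(n):
        roots[i], _ = uf.find(i)
    chain_ids = monomer_chain_map(topology)
    n_chains = topology.nA + topology.nB
    chain_labels = np.empty(n_chains, dtype=np.int64)
    # first monomer of each chain determines the chain's cluster
    starts = np.concatenate([
        np.arange(topology.nA) * topology.NA,
        topology.nA * topology.NA + np.arange(topology.nB) * topology.NB,
    ]).astype(np.int64)
    raw = roots[starts]
    # consistency: all monomers of a chain must share the root
    for c in range(n_chains):
        sel = chain_ids == c
        if not np.all(roots[sel] == roots[sel][0]):
            raise AssertionError("backbone not connected in cluster graph")
    _, chain_labels = np.unique(raw, return_inverse=True)
    sizes = np.bincount(chain_labels)
    order = np.sort(sizes)[::-1]
    spans = np.zeros(3, dtype=bool)
    for w in uf.winding.values():
        spans |= w
    return PercolationResult(
        chain_labels=chain_labels,
        spans_axis=spans,
        spanning=bool(spans.any()),
        largest_cluster=int(order[0]) if len(order) else 0,
        second_largest_cluster=int(order[1]) if len(order) > 1 else 0,
        monomer_labels=roots,
    )


def percolation_threshold_map(
    cA_grid: np.ndarray,
    cB_grid: np.ndarray,
    P: np.ndarray,
    level: float = 0.5,
    n_runs: np.ndarray | int | None = None,
) -> dict:
    """<P> heatmap summary and the level-contour by bilinear interpolation.

    ``P`` has shape (len(cB_grid), len(cA_grid)) holding mean percolation
    probabilities; the 0.5-contour is extracted with marching squares
    (bilinear interpolation on cell edges).  Returns a dict with the contour
    vertex list in (cA, cB) coordinates and the standard error per grid
    point (binomial, if ``n_runs`` given).
    """
    from skimage import measure

    P = np.asarray(P, dtype=float)
    if P.shape != (len(cB_grid), len(cA_grid)):
        raise ValueError("P must have shape (len(cB_grid), len(cA_grid))")
    se = None
    if n_runs is not None:
        n_runs = np.broadcast_to(np.asarray(n_runs, dtype=float), P.shape)
        se = np.sqrt(np.clip(P * (1 - P), 0, None) / np.maximum(n_runs, 1))
    if np.all(P <= level) or np.all(P >= level):
        if np.allclose(P, level):
            return {"contours": [], "P": P, "se": se, "degenerate": True}
        return {"contours": [], "P": P, "se": se, "degenerate": False}
    contours = measure.find_contours(P, level)
    out = []
    for c in contours:
        # c[:, 0] indexes cB_grid rows, c[:, 1] indexes cA_grid columns
        cb = np.interp(c[:, 0], np.arange(len(cB_grid)), cB_grid)
        ca = np.interp(c[:, 1], np.arange(len(cA_grid)), cA_grid)
        out.append(np.column_stack([ca, cb]))
    return {"contours": out, "P": P, "se": se, "degenerate": False}


# ---------------------------------------------------------------------------
# binding motifs
# ---------------------------------------------------------------------------

@dataclass
class MotifStats:
    """Per-frame counts of A-chain binding motifs."""

    n_bridge: int
    n_loop: int
    n_single: int
    n_unbound: int
    bridges_per_b_chain: float
    bound_a_per_b_chain: float

    @property
    def total(self) -> int:
        return self.n_bridge + self.n_loop + self.n_single + self.n_unbound


def classify_motifs(frame: TrajectoryFrame, topology: SystemTopology) -> MotifStats:
    """Classify every A-chain by its crosslinks to B-chains.

    0 bonds: unbound; 1 bond: singly bound; >=2 bonds all to one B-chain:
    loop; >=2 bonds to >=2 distinct B-chains: bridge.
    """
    chain_ids = monomer_chain_map(topology)
    partners_of_a: dict[int, list[int]] = {c: [] for c in range(topology.nA)}
    a_count_per_b: dict[int, set[int]] = {}
    for a, b in frame.pairs:
        # registered pairs store (lower id, higher id); identify the A side
        ca, cb = int(chain_ids[a]), int(chain_ids[b])
        if ca < topology.nA:
            a_mono, b_mono = a, b
            a_chain, b_chain = ca, cb
        else:
            a_mono, b_mono = b, a
            a_chain, b_chain = cb, ca
        partners_of_a[a_chain].append(b_chain)
        a_count_per_b.setdefault(b_chain, set()).add(a_chain)
    n_bridge = n_loop = n_single = n_unbound = 0
    bridges_touching_b: dict[int, int] = {}
    for a_chain, b_chains in partners_of_a.items():
        if len(b_chains) == 0:
            n_unbound += 1
        elif len(b_chains) == 1:
            n_single += 1
        elif len(set(b_chains)) == 1:
            n_loop += 1
        else:
            n_bridge += 1
            for bc in set(b_chains):
                bridges_touching_b[bc] = bridges_touching_b.get(bc, 0) + 1
    nb = max(topology.nB, 1)
    return MotifStats(
        n_bridge=n_bridge, n_loop=n_loop, n_single=n_single,
        n_unbound=n_unbound,
        bridges_per_b_chain=sum(bridges_touching_b.values()) / nb,
        bound_a_per_b_chain=sum(len(s) for s in a_count_per_b.values()) / nb,
    )


# ---------------------------------------------------------------------------
# density profiles and coexistence
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Mean density per species along one axis, averaged over frames."""

    axis: int
    centers: np.ndarray
    density: dict          # name -> mean density [sigma^-3]
    se: dict               # name -> standard error over frames
    bin_width: float
    box: tuple[float, float, float]
    n_frames: int


def _recenter_shift(frame: TrajectoryFrame, topology: SystemTopology,
                    axis: int) -> float:
    """Shift placing the largest bond-network cluster's centre of mass at the
    box centre along ``axis`` (circular mean, robust under periodicity)."""
    res = connectivity_and_percolation(frame, topology)
    sizes = np.bincount(res.chain_labels)
    big = np.argmax(sizes)
    chain_ids = monomer_chain_map(topology)
    sel = res.chain_labels[chain_ids] == big
    L = frame.box[axis]
    theta = frame.positions[sel, axis] / L * 2.0 * np.pi
    mean_angle = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    com = (mean_angle / (2.0 * np.pi)) % 1.0 * L
    return 0.5 * L - com


def density_profile(
    trajectory: Trajectory,
    axis: int = 1,
    bin_width: float = 1.0,
    recenter: bool = True,
) -> DensityProfile:
    """Per-species density histogram along ``axis``, averaged over frames.

    With ``recenter`` the largest cluster's centre of mass is shifted to the
    box centre in every frame before binning, which keeps slab interfaces
    sharp in the average.  Densities are reported for species 'A', 'B',
    their crosslinkable/neutral sub-classes, and 'total'.
    """
    if len(trajectory.frames) == 0:
        raise ValueError("empty trajectory")
    topo = trajectory.topology
    box = trajectory.frames[0].box
    L = box[axis]
    nbins = max(1, int(round(L / bin_width)))
    width = L / nbins
    edges = np.linspace(0.0, L, nbins + 1)
    area = np.prod([box[d] for d in range(3) if d != axis])
    from revlink.simulate import build_system  # species/link_type layout
    layout = build_system(topo)
    classes = {
        "A": layout.species == 0,
        "B": layout.species == 1,
        "A_crosslinkable": layout.link_type == 1,
        "B_crosslinkable": layout.link_type == 2,
        "B_neutral": (layout.species == 1) & (layout.link_type == 0),
        "total": np.ones(topo.n_monomers, dtype=bool),
    }
    sums = {k: [] for k in classes}
    for fr in trajectory.frames:
        shift = _recenter_shift(fr, topo, axis) if recenter else 0.0
        x = (fr.positions[:, axis] + shift) % L
        for name, mask in classes.items():
            h, _ = np.histogram(x[mask], bins=edges)
            sums[name].append(h / (width * area))
    density = {}
    se = {}
    nf = len(trajectory.frames)
    for name in classes:
        arr = np.asarray(sums[name])
        density[name] = arr.mean(axis=0)
        se[name] = arr.std(axis=0, ddof=1) / np.sqrt(nf) if nf > 1 \
            else np.zeros(nbins)
    return DensityProfile(axis=axis, centers=0.5 * (edges[:-1] + edges[1:]),
                          density=density, se=se, bin_width=width, box=box,
                          n_frames=nf)


@dataclass
class PhasePointEstimate:
    """Coexisting dilute and dense branch densities with standard errors."""

    coexistence: bool
    cA_dilute: float = np.nan
    cB_dilute: float = np.nan
    cA_dense: float = np.nan
    cB_dense: float = np.nan
    se_dilute: tuple[float, float] = (np.nan, np.nan)
    se_dense: tuple[float, float] = (np.nan, np.nan)
    interface_width: float = np.nan
    diagnostics: dict = field(default_factory=dict)

    @property
    def tie_line(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return ((self.cA_dilute, self.cB_dilute),
                (self.cA_dense, self.cB_dense))


def _two_tanh(y, rho_dil, rho_den, y1, y2, w):
    return rho_dil + 0.5 * (rho_den - rho_dil) * (
        np.tanh((y - y1) / w) - np.tanh((y - y2) / w))


def coexistence_from_profile(profile: DensityProfile,
                             contrast_sigma: float = 3.0) -> PhasePointEstimate:
    """Coexisting densities from a slab profile via a two-interface tanh fit.

    The total profile is fitted with a dense slab between two tanh
    interfaces; plateau densities per species are then measured from bins
    farther than two fitted widths from either interface.  Reports
    "no coexistence" when the plateau contrast is below ``contrast_sigma``
    times the combined standard error, or when the fit fails.
    """
    y = profile.centers
    rho = profile.density["total"]
    L = profile.box[profile.axis]
    lo = max(float(np.min(rho)), 0.0)
    hi = max(float(np.max(rho)), 1e-12)
    p0 = (lo, hi, 0.5 * L - 0.15 * L, 0.5 * L + 0.15 * L, 2.0)
    try:
        popt, pcov = curve_fit(
            _two_tanh, y, rho, p0=p0,
            bounds=([0, 0, 0, 0, 0.2], [np.inf, np.inf, L, L, 0.5 * L]),
            maxfev=20000)
    except Exception as exc:  # non-converged fit -> no coexistence
        return PhasePointEstimate(coexistence=False,
                                  diagnostics={"fit_error": str(exc)})
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    rho_dil, rho_den, y1, y2, w = popt
    if y2 < y1:
        y1, y2 = y2, y1
    # plateau bins at least 3 fitted widths from either interface: the tanh
    # tail at 2w still carries ~2% of the contrast, at 3w only ~0.5%
    margin = 3.0 * w
    dense_sel = (y > y1 + margin) & (y < y2 - margin)
    dil_sel = (y < y1 - margin) | (y > y2 + margin)
    if dense_sel.sum() < 2:  # narrow slab: fall back to the 2w margin
        dense_sel = (y > y1 + 2 * w) & (y < y2 - 2 * w)
    if dense_sel.sum() < 2 or dil_sel.sum() < 2:
        return PhasePointEstimate(coexistence=False,
                                  diagnostics={"reason": "slab too narrow"})

    def branch(sel, fit_se):
        # branch SE combines the bin-average error with the fitted plateau
        # parameter's own uncertainty (the bin selection depends on the
        # fitted interfaces, so the bin average alone underestimates)
        out = {}
        tot_mean = max(profile.density["total"][sel].mean(), 1e-300)
        for sp in ("A", "B", "total"):
            m = profile.density[sp][sel].mean()
            s_bins = np.sqrt(np.mean(profile.se[sp][sel] ** 2)
                             / max(sel.sum(), 1))
            share = m / tot_mean
            out[sp] = (m, float(np.hypot(s_bins, share * fit_se)))
        return out

    den = branch(dense_sel, perr[1])
    dil = branch(dil_sel, perr[0])
    contrast = den["total"][0] - dil["total"][0]
    err = np.hypot(den["total"][1], dil["total"][1])
    if contrast < contrast_sigma * max(err, 1e-12):
        return PhasePointEstimate(
            coexistence=False,
            diagnostics={"contrast": contrast, "se": err})
    return PhasePointEstimate(
        coexistence=True,
        cA_dilute=dil["A"][0], cB_dilute=dil["B"][0],
        cA_dense=den["A"][0], cB_dense=den["B"][0],
        se_dilute=(dil["A"][1], dil["B"][1]),
        se_dense=(den["A"][1], den["B"][1]),
        interface_width=float(w),
        diagnostics={"y1": y1, "y2": y2, "rho_fit": (rho_dil, rho_den)})


def block_distribution_coexistence(
    trajectory: Trajectory, block_size: float,
) -> PhasePointEstimate:
    """Coexistence from the distribution of densities in cubic sub-blocks.

    A bimodal block-density distribution signals coexistence; the two peak
    positions give the coexisting total densities, and per-species branch
    densities follow from blocks assigned to the low/high mode.
    """
    from scipy.signal import find_peaks

    if len(trajectory.frames) == 0:
        raise ValueError("empty trajectory")
    box = np.asarray(trajectory.frames[0].box)
    nblocks = np.floor(box / block_size).astype(int)
    if np.any(nblocks < 1):
        raise ValueError("block larger than box")
    if np.prod(nblocks) < 2:
        raise ValueError("block size leaves a single sample; choose smaller blocks")
    cell = box / nblocks
    vol = float(np.prod(cell))
    from revlink.simulate import build_system
    layout = build_system(trajectory.topology)
    is_a = layout.species == 0
    dens_tot, dens_a, dens_b = [], [], []
    for fr in trajectory.frames:
        idx = np.minimum((fr.positions / cell).astype(int), nblocks - 1)
        flat = (idx[:, 0] * nblocks[1] + idx[:, 1]) * nblocks[2] + idx[:, 2]
        nb_tot = np.bincount(flat, minlength=np.prod(nblocks))
        nb_a = np.bincount(flat[is_a], minlength=np.prod(nblocks))
        dens_tot.append(nb_tot / vol)
        dens_a.append(nb_a / vol)
        dens_b.append((nb_tot - nb_a) / vol)
    dens_tot = np.concatenate(dens_tot)
    dens_a = np.concatenate(dens_a)
    dens_b = np.concatenate(dens_b)
    hist, edges = np.histogram(dens_tot, bins=60)
    smooth = np.convolve(hist, np.ones(5) / 5.0, mode="same")
    peaks, _ = find_peaks(smooth, prominence=0.1 * smooth.max())
    if len(peaks) < 2:
        return PhasePointEstimate(coexistence=False,
                                  diagnostics={"n_peaks": int(len(peaks))})
    # two most prominent peaks, which must be separated by a genuine valley
    peaks = np.sort(peaks[np.argsort(smooth[peaks])[::-1][:2]])
    valley = smooth[peaks[0]:peaks[1] + 1].min()
    if valley > 0.5 * min(smooth[peaks[0]], smooth[peaks[1]]):
        return PhasePointEstimate(coexistence=False,
                                  diagnostics={"reason": "no valley between modes"})
    centers = 0.5 * (edges[:-1] + edges[1:])
    p_lo, p_hi = sorted(centers[peaks])
    # species densities from blocks near each mode only; blocks straddling
    # an interface populate the valley and would bias the branch means
    band = 0.25 * (p_hi - p_lo)
    lo = np.abs(dens_tot - p_lo) < band
    hi = np.abs(dens_tot - p_hi) < band

    def stats(sel, arr):
        m = arr[sel].mean()
        s = arr[sel].std(ddof=1) / np.sqrt(max(sel.sum(), 2))
        return m, s

    a_lo, sa_lo = stats(lo, dens_a)
    b_lo, sb_lo = stats(lo, dens_b)
    a_hi, sa_hi = stats(hi, dens_a)
    b_hi, sb_hi = stats(hi, dens_b)
    return PhasePointEstimate(
        coexistence=True,
        cA_dilute=a_lo, cB_dilute=b_lo, cA_dense=a_hi, cB_dense=b_hi,
        se_dilute=(sa_lo, sb_lo), se_dense=(sa_hi, sb_hi),
        diagnostics={"peak_densities": (p_lo, p_hi)})


# ---------------------------------------------------------------------------
# structure factor and RDF
# ---------------------------------------------------------------------------

def structure_factor(
    frames: list[TrajectoryFrame] | TrajectoryFrame,
    subset: np.ndarray | None = None,
    k_max: float = 6.0,
    n_shells: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Spherically binned static structure factor over commensurate k-vectors.

    S(k) = <|sum_j exp(i k.r_j)|^2> / N over wavevectors k = 2 pi n / L with
    integer n and 0 < |k| <= k_max, averaged over frames and binned into
    ``n_shells`` shells.  Returns (shell centers, S).
    """
    if isinstance(frames, TrajectoryFrame):
        frames = [frames]
    if not frames:
        raise ValueError("no frames")
    box = np.asarray(frames[0].box)
    nmax = np.floor(k_max * box / (2 * np.pi)).astype(int)
    grids = np.meshgrid(*(np.arange(-m, m + 1) for m in nmax), indexing="ij")
    nvec = np.stack([g.ravel() for g in grids], axis=1)
    nvec = nvec[np.any(nvec != 0, axis=1)]
    kvec = 2 * np.pi * nvec / box
    kabs = np.linalg.norm(kvec, axis=1)
    keep = kabs <= k_max
    kvec, kabs = kvec[keep], kabs[keep]
    edges = np.linspace(0, k_max, n_shells + 1)
    which = np.digitize(kabs, edges) - 1
    acc = np.zeros(len(kvec))
    for fr in frames:
        r = fr.positions if subset is None else fr.positions[subset]
        if len(r) == 0:
            raise ValueError("empty subset")
        phase = r @ kvec.T
        amp = np.exp(1j * phase).sum(axis=0)
        acc += (amp.real ** 2 + amp.imag ** 2) / len(r)
    acc /= len(frames)
    S = np.full(n_shells, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for s in range(n_shells):
        sel = which == s
        if sel.any():
            S[s] = acc[sel].mean()
    good = ~np.isnan(S)
    return centers[good], S[good]


def rdf(
    frames: list[TrajectoryFrame] | TrajectoryFrame,
    subset_a: np.ndarray | None = None,
    subset_b: np.ndarray | None = None,
    r_max: float | None = None,
    dr: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-image radial distribution function g(r).

    ``subset_a``/``subset_b`` select the two particle classes (indices or
    boolean masks); identical subsets give the self-RDF.  ``r_max`` must not
    exceed half the shortest box side.
    """
    if isinstance(frames, TrajectoryFrame):
        frames = [frames]
    if not frames:
        raise ValueError("no frames")
    box = np.asarray(frames[0].box)
    half = 0.5 * float(box.min())
    if r_max is None:
        r_max = half
    if r_max > half + 1e-9:
        raise ValueError("r_max must be <= half the shortest box side")
    nbins = int(np.ceil(r_max / dr))
    edges = np.linspace(0, nbins * dr, nbins + 1)
    hist = np.zeros(nbins)
    norm_pairs = 0.0
    V = float(np.prod(box))
    for fr in frames:
        ra = fr.positions if subset_a is None else fr.positions[subset_a]
        rb = fr.positions if subset_b is None else fr.positions[subset_b]
        same = subset_b is None and subset_a is None or (
            subset_a is not None and subset_b is not None
            and np.array_equal(subset_a, subset_b))
        d = ra[:, None, :] - rb[None, :, :]
        d -= box * np.rint(d / box)
        r = np.sqrt((d * d).sum(axis=-1))
        if same:
            iu = np.triu_indices(len(ra), k=1)
            r = r[iu]
            norm_pairs += len(ra) * (len(ra) - 1) / 2.0
        else:
            r = r.ravel()
            norm_pairs += len(ra) * len(rb)
        h, _ = np.histogram(r, bins=edges)
        hist += h
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = norm_pairs * shell / V
    g = np.divide(hist, ideal, out=np.zeros_like(hist), where=ideal > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, g


# ---------------------------------------------------------------------------
# chain statistics
# ---------------------------------------------------------------------------

@dataclass
class ChainStatistics:
    """Conformational statistics of one chain species."""

    Rg: float                      # sqrt(<Rg^2>) [sigma]
    Rg2_se: float
    Ree2: float                    # <Ree^2> [sigma^2]
    persistence_length: float      # [sigma]
    mean_bond_length: float        # [sigma]
    ee_decorrelation_time: float   # integrated ACF time [t0]
    overlap_concentration: float   # N / ((4/3) pi Rg^3) [sigma^-3]
    bond_correlation: tuple = field(repr=False, default=())


def chain_statistics(
    trajectory: Trajectory,
    species: str = "B",
    fit_cut: float = 0.2,
) -> ChainStatistics:
    """Rg, persistence length, end-to-end decorrelation and c* from a
    (typically dilute or single-chain) trajectory.

    The persistence length comes from an exponential fit of the bond-vector
    orientational correlation <u(s).u(s+Delta)> against contour distance,
    restricted to the initial decay (correlations above ``fit_cut``).  The
    overlap concentration uses c* = N / ((4/3) pi <Rg^2>^(3/2)).
    """
    topo = trajectory.topology
    if species == "B":
        n_chain, length, offset = topo.nB, topo.NB, topo.nA * topo.NA
    else:
        n_chain, length, offset = topo.nA, topo.NA, 0
    if n_chain == 0:
        raise ValueError(f"no {species}-chains in topology")
    if len(trajectory.frames) < 2:
        raise ValueError("need at least two frames")
    rg2_samples = []
    ree_vectors = []   # (frame, chain, 3)
    bond_corr_acc = np.zeros(length - 1)
    bond_corr_cnt = np.zeros(length - 1)
    blen = []
    for fr in trajectory.frames:
        u = fr.unwrapped
        ree_f = []
        for c in range(n_chain):
            r = u[offset + c * length: offset + (c + 1) * length]
            com = r.mean(axis=0)
            rg2_samples.append(((r - com) ** 2).sum(axis=1).mean())
            ree_f.append(r[-1] - r[0])
            bonds = np.diff(r, axis=0)
            lb = np.linalg.norm(bonds, axis=1)
            blen.append(lb.mean())
            ub = bonds / lb[:, None]
            for delta in range(length - 1):
                dots = (ub[: len(ub) - delta] * ub[delta:]).sum(axis=1)
                bond_corr_acc[delta] += dots.sum()
                bond_corr_cnt[delta] += len(dots)
        ree_vectors.append(ree_f)
    rg2 = np.asarray(rg2_samples)
    ree = np.asarray(ree_vectors)  # (F, C, 3)
    corr = bond_corr_acc / np.maximum(bond_corr_cnt, 1)
    b_mean = float(np.mean(blen))

    # persistence length: fit log C(delta) = -delta * b / lp on initial decay
    deltas = np.arange(len(corr))
    sel = (corr > fit_cut) & (deltas > 0)
    if sel.sum() < 2:
        if len(corr) > 1 and corr[1] < fit_cut:
            # instant decorrelation (freely jointed limit): lp from the
            # nearest-neighbour correlation alone
            lp = float(-b_mean / np.log(max(corr[1], 1e-12)))
        else:
            lp = float(length * b_mean)  # no resolvable decay (rod-like)
    else:
        slope = np.polyfit(deltas[sel] * b_mean, np.log(corr[sel]), 1)[0]
        lp = float(-1.0 / slope) if slope < 0 else float(length * b_mean)

    # end-to-end autocorrelation time (integrated, averaged over chains)
    f = ree.shape[0]
    times = np.asarray([fr.time for fr in trajectory.frames])
    dt_frame = float(np.mean(np.diff(times))) if f > 1 else 1.0
    acf = np.zeros(f)
    for c in range(ree.shape[1]):
        v = ree[:, c, :] - ree[:, c, :].mean(axis=0)
        for lag in range(f):
            acf[lag] += (v[: f - lag] * v[lag:]).sum() / (f - lag)
    acf /= acf[0] if acf[0] > 0 else 1.0
    # integrate to the first zero crossing
    upto = np.argmax(acf <= 0) or f
    tau = float((0.5 + acf[1:upto].sum()) * dt_frame)

    rg2_mean = float(rg2.mean())
    # frames are correlated; use tau to deflate the effective sample count
    n_eff = max(1.0, len(rg2) * min(1.0, dt_frame / max(tau, dt_frame)))
    rg2_se = float(rg2.std(ddof=1) / np.sqrt(n_eff)) if len(rg2) > 1 else np.nan
    cstar = length / (4.0 / 3.0 * np.pi * rg2_mean ** 1.5)
    return ChainStatistics(
        Rg=float(np.sqrt(rg2_mean)),
        Rg2_se=rg2_se,
        Ree2=float((ree ** 2).sum(axis=2).mean()),
        persistence_length=lp,
        mean_bond_length=b_mean,
        ee_decorrelation_time=tau,
        overlap_concentration=float(cstar),
        bond_correlation=tuple(corr),
    )
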