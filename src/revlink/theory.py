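"""Mean-field Semenov-Rubinstein theory of the reversibly crosslinked
A/B mixture.

The free-energy density (per kBT, per sigma^3) balances chain translational
entropy, a quadratic excluded-volume repulsion, and the pairing free energy
of the crosslinkable sites:

    f(cA, cB) = (cA/NA)[ln(cA/NA) - 1] + (cB/NB)[ln(cB/NB) - 1]
              + (vex/2)(cA + cB)^2
              + GammaA ln XA + GammaB ln XB + b,

where GammaX = fX cX / NX are crosslinkable-site densities, b is the bond
density solving the mass-action law (GammaA - b)(GammaB - b) = K b, and
XA = (GammaA - b)/GammaA, XB likewise, are the free-site fractions.  The
association term is the Wertheim one-bond-per-site form
GammaX (ln XX - XX/2 + 1/2) summed over species, rewritten with b.  The
only two parameters beyond the topology are the dissociation constant K and
the effective repulsion parameter vex.

Without association (K -> infinity) f is strictly convex and the mixture
never demixes; phase separation is driven entirely by the pairing entropy.
The module constructs binodals with tie lines by convex-envelope seeding
plus Newton refinement of the equal-chemical-potential / equal-pressure
conditions, the Flory-Stockmayer percolation line, the stoichiometric line,
and the athermal K -> 0 limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root
from scipy.spatial import ConvexHull

__all__ = [
    "TheoryParameters",
    "AssociationState",
    "TieLine",
    "TheoreticalPhaseDiagram",
    "bond_density",
    "free_energy_density",
    "chemical_potentials_pressure",
    "construct_binodal",
    "two_phase_mask",
    "percolation_line",
    "athermal_limit_diagram",
    "stoichiometric_line",
]


@dataclass(frozen=True)
class TheoryParameters:
    """Topology plus the two thermodynamic parameters K and vex."""

    NA: int = 7
    NB: int = 65
    fA: int = 3
    fB: int = 32
    K: float = 0.001257      # dissociation constant [sigma^-3]
    vex: float = 1.73        # effective repulsion parameter [sigma^3]

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.vex <= 0:
            raise ValueError("vex must be positive")
        if min(self.NA, self.NB, self.fA, self.fB) < 1:
            raise ValueError("chain parameters must be positive")

    def site_densities(self, cA, cB):
        return self.fA * np.asarray(cA) / self.NA, \
            self.fB * np.asarray(cB) / self.NB


@dataclass(frozen=True)
class AssociationState:
    """Solution of the mass-action pairing law at one composition."""

    GammaA: float
    GammaB: float
    b: float
    pA: float        # bound fraction of A-sites
    pB: float


def bond_density(GammaA, GammaB, K) -> np.ndarray | float:
    """Bond density: unique root of (GammaA - b)(GammaB - b) = K b in
    [0, min(GammaA, GammaB)].

    Uses the numerically stable form b = 2 GA GB / (S + sqrt(S^2 - 4 GA GB))
    with S = GA + GB + K, which handles K = 0 (b -> min(GA, GB)) and
    K -> infinity (b -> GA GB / K -> 0) without cancellation.
    """
    GA = np.asarray(GammaA, dtype=float)
    GB = np.asarray(GammaB, dtype=float)
    if np.any(GA < 0) or np.any(GB < 0) or K < 0:
        raise ValueError("site densities and K must be non-negative")
    S = GA + GB + K
    disc = S * S - 4.0 * GA * GB
    denom = S + np.sqrt(np.maximum(disc, 0.0))
    b = np.divide(2.0 * GA * GB, denom, out=np.zeros_like(S),
                  where=denom > 0)
    return b if b.ndim else float(b)


def association_state(GammaA: float, GammaB: float, K: float) -> AssociationState:
    b = bond_density(GammaA, GammaB, K)
    pA = b / GammaA if GammaA > 0 else 0.0
    pB = b / GammaB if GammaB > 0 else 0.0
    return AssociationState(GammaA=GammaA, GammaB=GammaB, b=float(b),
                            pA=float(pA), pB=float(pB))


def _xlogx(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def free_energy_density(cA, cB, params: TheoryParameters):
    """Mean-field free-energy density f(cA, cB) [kBT sigma^-3].

    Vectorised; the limits cX -> 0 are handled analytically (x ln x -> 0 and
    the association term of an absent species vanishes).
    """
    cA = np.asarray(cA, dtype=float)
    cB = np.asarray(cB, dtype=float)
    scalar = cA.ndim == 0 and cB.ndim == 0
    cA, cB = np.broadcast_arrays(np.atleast_1d(cA), np.atleast_1d(cB))
    if np.any(cA < 0) or np.any(cB < 0):
        raise ValueError("densities must be non-negative")
    nA = cA / params.NA
    nB = cB / params.NB
    ideal = _xlogx(nA) - nA + _xlogx(nB) - nB
    ev = 0.5 * params.vex * (cA + cB) ** 2
    GA, GB = params.site_densities(cA, cB)
    b = np.asarray(bond_density(GA, GB, params.K))
    assoc = np.zeros_like(b)
    withA = GA > 0
    withB = GB > 0
    # free-site fractions; when K>0 these are strictly positive
    with np.errstate(divide="ignore", invalid="ignore"):
        XA = np.where(withA, (GA - b) / np.where(withA, GA, 1.0), 1.0)
        XB = np.where(withB, (GB - b) / np.where(withB, GB, 1.0), 1.0)
    XA = np.clip(XA, 1e-300, None)
    XB = np.clip(XB, 1e-300, None)
    assoc = np.where(withA, GA * np.log(XA), 0.0) \
        + np.where(withB, GB * np.log(XB), 0.0) + b
    f = ideal + ev + assoc
    return float(f[0]) if scalar else f.reshape(np.broadcast(cA, cB).shape)


def chemical_potentials_pressure(cA, cB, params: TheoryParameters):
    """(muA, muB, Pi): chemical potentials per monomer and osmotic pressure.

    muA = df/dcA = (1/NA) ln(cA/NA) + vex (cA + cB) + (fA/NA) ln XA (the
    association contribution reduces to ln XA by the mass-action envelope),
    and Pi = cA muA + cB muB - f.
    """
    cA = float(cA)
    cB = float(cB)
    if cA <= 0 or cB <= 0:
        raise ValueError("chemical potentials require strictly positive densities")
    GA, GB = params.site_densities(cA, cB)
    b = bond_density(GA, GB, params.K)
    XA = (GA - b) / GA
    XB = (GB - b) / GB
    XA = max(XA, 1e-300)
    XB = max(XB, 1e-300)
    muA = (np.log(cA / params.NA) / params.NA
           + params.vex * (cA + cB)
           + params.fA / params.NA * np.log(XA))
    muB = (np.log(cB / params.NB) / params.NB
           + params.vex * (cA + cB)
           + params.fB / params.NB * np.log(XB))
    f = free_energy_density(cA, cB, params)
    Pi = cA * muA + cB * muB - f
    return float(muA), float(muB), float(Pi)


# ---------------------------------------------------------------------------
# binodal construction
# ---------------------------------------------------------------------------

@dataclass
class TieLine:
    """A refined pair of coexisting compositions."""

    dilute: tuple[float, float]
    dense: tuple[float, float]
    residual: float

    @property
    def length(self) -> float:
        return float(np.hypot(self.dense[0] - self.dilute[0],
                              self.dense[1] - self.dilute[1]))

    @property
    def midpoint(self) -> tuple[float, float]:
        return (0.5 * (self.dilute[0] + self.dense[0]),
                0.5 * (self.dilute[1] + self.dense[1]))


@dataclass
class TheoreticalPhaseDiagram:
    """Binodal points, tie lines, critical points and auxiliary lines."""

    params: TheoryParameters
    tie_lines: list[TieLine] = field(default_factory=list)
    critical_points: list[tuple[float, float]] = field(default_factory=list)
    closed_loop: bool = False

    @property
    def binodal_points(self) -> np.ndarray:
        pts = [tl.dilute for tl in self.tie_lines] + \
            [tl.dense for tl in self.tie_lines]
        return np.asarray(pts).reshape(-1, 2)

    @property
    def has_coexistence(self) -> bool:
        return len(self.tie_lines) > 0


def _default_grid(c_min: float = 3e-5, c_max: float = 0.4, n: int = 160):
    return np.geomspace(c_min, c_max, n)


def _tie_candidates(params: TheoryParameters, grid_a, grid_b):
    """Coexistence seeds from the lower convex envelope of (cA, cB, f)."""
    A, B = np.meshgrid(grid_a, grid_b, indexing="ij")
    pts2 = np.column_stack([A.ravel(), B.ravel()])
    F = free_energy_density(pts2[:, 0], pts2[:, 1], params)
    # scale the f axis to O(1) so hull tolerances behave
    fscale = np.max(np.abs(F)) or 1.0
    cloud = np.column_stack([pts2, F / fscale])
    hull = ConvexHull(cloud, qhull_options="Qt")
    lower = hull.equations[:, 2] < -1e-10  # facet normal points down in f
    # local grid spacing at each point (geometric grid)
    ra = grid_a[1] / grid_a[0]
    rb = grid_b[1] / grid_b[0]
    seeds = []
    for simplex in hull.simplices[lower]:
        for e in ((0, 1), (0, 2), (1, 2)):
            p = pts2[simplex[e[0]]]
            q = pts2[simplex[e[1]]]
            # an edge is a tie-line candidate when it is much longer than
            # the local sampling spacing at both endpoints
            loc_p = max(p[0] * (ra - 1.0), p[1] * (rb - 1.0))
            loc_q = max(q[0] * (ra - 1.0), q[1] * (rb - 1.0))
            length = np.hypot(p[0] - q[0], p[1] - q[1])
            if length > 4.0 * max(loc_p, loc_q):
                seeds.append((p, q))
    return seeds


def _refine_tie_line(params: TheoryParameters, p, q):
    """Newton refinement of equal-mu/equal-Pi between the two endpoints.

    Unknowns are log densities of both endpoints; the fourth equation pins
    the tie-line midpoint to the seed midpoint along the tie direction.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m0 = 0.5 * (p + q)
    t = q - p
    norm = np.linalg.norm(t)
    if norm == 0:
        return None
    t = t / norm

    def residuals(u):
        if np.any(u > 3.0) or np.any(u < -40.0) or not np.all(np.isfinite(u)):
            return np.full(4, 1e6)
        c1 = np.exp(u[:2])
        c2 = np.exp(u[2:])
        try:
            with np.errstate(all="ignore"):
                muA1, muB1, Pi1 = chemical_potentials_pressure(c1[0], c1[1], params)
                muA2, muB2, Pi2 = chemical_potentials_pressure(c2[0], c2[1], params)
        except (ValueError, FloatingPointError):
            return np.full(4, 1e6)
        out = np.array([
            muA1 - muA2,
            muB1 - muB2,
            Pi1 - Pi2,
            np.dot(0.5 * (c1 + c2) - m0, t),
        ])
        if not np.all(np.isfinite(out)):
            return np.full(4, 1e6)
        return out

    u0 = np.log(np.concatenate([p, q]))
    sol = root(residuals, u0, method="hybr", options={"xtol": 1e-13})
    if not sol.success:
        return None
    res = np.max(np.abs(residuals(sol.x)[:3]))
    if res > 1e-8:
        return None
    c1 = np.exp(sol.x[:2])
    c2 = np.exp(sol.x[2:])
    if c1.sum() > c2.sum():
        c1, c2 = c2, c1
    sep = np.linalg.norm(c2 - c1)
    if sep < 1e-6 or sep < 0.05 * norm:
        return None  # collapsed onto the trivial solution
    return TieLine(dilute=(float(c1[0]), float(c1[1])),
                   dense=(float(c2[0]), float(c2[1])), residual=float(res))


def construct_binodal(
    params: TheoryParameters,
    c_min: float = 3e-5,
    c_max: float = 0.4,
    n_grid: int = 160,
    max_ties: int = 80,
) -> TheoreticalPhaseDiagram:
    """Binodal with tie lines by convex-envelope seeding + Newton refinement.

    Stage 1 samples f on a geometric (cA, cB) grid and takes the lower
    convex envelope of the surface; facet edges much longer than the local
    grid spacing seed tie lines.  Stage 2 refines each seed by solving
    muA, muB and Pi equality between the endpoints.  Critical points are
    estimated as the midpoints of the shortest tie lines at the two ends of
    the refined family; the diagram is flagged as a closed loop when the
    dense branch stays inside the sampled window.
    """
    grid = _default_grid(c_min, c_max, n_grid)
    seeds = _tie_candidates(params, grid, grid)
    diagram = TheoreticalPhaseDiagram(params=params)
    if not seeds:
        return diagram
    # thin seeds: keep at most max_ties spread over the family
    if len(seeds) > max_ties:
        idx = np.linspace(0, len(seeds) - 1, max_ties).astype(int)
        order = np.argsort([0.5 * (s[0][1] + s[1][1]) for s in seeds])
        seeds = [seeds[i] for i in np.asarray(order)[idx]]
    ties = []
    for p, q in seeds:
        tl = _refine_tie_line(params, p, q)
        if tl is not None:
            ties.append(tl)
    if not ties:
        return diagram
    # deduplicate by dilute endpoint
    uniq: list[TieLine] = []
    for tl in ties:
        dup = False
        for u in uniq:
            if (abs(tl.dilute[0] - u.dilute[0])
                    <= 0.02 * max(u.dilute[0], 1e-12)
                    and abs(tl.dilute[1] - u.dilute[1])
                    <= 0.02 * max(u.dilute[1], 1e-12)):
                dup = True
                break
        if not dup:
            uniq.append(tl)
    # order the family along the dilute branch
    uniq.sort(key=lambda tl: np.arctan2(tl.dilute[1], tl.dilute[0]))
    diagram.tie_lines = uniq
    if len(uniq) >= 3:
        diagram.critical_points = [uniq[0].midpoint, uniq[-1].midpoint]
    dense = np.asarray([tl.dense for tl in uniq])
    diagram.closed_loop = (len(uniq) >= 3
                           and dense.max() < 0.95 * c_max
                           and len(diagram.critical_points) == 2)
    return diagram


def two_phase_mask(
    params: TheoryParameters,
    grid_a: np.ndarray,
    grid_b: np.ndarray,
) -> np.ndarray:
    """Boolean (len(grid_a), len(grid_b)) mask of compositions that demix.

    A sampled composition is inside the coexistence region iff it is not a
    vertex of the lower convex envelope of the free-energy surface: interior
    points lie strictly above the envelope and split into the facet
    endpoints.  This is coarser than the refined binodal but is robust for
    region queries (reentrance scans, enclosure comparisons).
    """
    A, B = np.meshgrid(grid_a, grid_b, indexing="ij")
    pts2 = np.column_stack([A.ravel(), B.ravel()])
    F = free_energy_density(pts2[:, 0], pts2[:, 1], params)
    fscale = np.max(np.abs(F)) or 1.0
    cloud = np.column_stack([pts2, F / fscale])
    hull = ConvexHull(cloud, qhull_options="Qt")
    # vertices of the lower envelope only: collect vertices of facets whose
    # normal points down in f
    lower = hull.equations[:, 2] < -1e-10
    stable = np.zeros(len(pts2), dtype=bool)
    stable[np.unique(hull.simplices[lower])] = True
    return ~stable.reshape(A.shape)


def percolation_line(
    params: TheoryParameters,
    c_min: float = 3e-5,
    c_max: float = 0.4,
    n_grid: int = 300,
) -> list[np.ndarray]:
    """Flory-Stockmayer gel line of the alternating A-B network.

    Gelation requires (fA - 1)(fB - 1) pA pB = 1, with the bound-site
    fractions pX = b / GammaX from the mass-action law.  Returns contour
    polylines in the (cA, cB) plane (may be empty).
    """
    from skimage import measure

    if params.fA < 2 or params.fB < 2:
        raise ValueError("percolation requires at least 2 crosslinkers per chain")
    grid = _default_grid(c_min, c_max, n_grid)
    A, B = np.meshgrid(grid, grid, indexing="ij")
    GA, GB = params.site_densities(A, B)
    b = np.asarray(bond_density(GA, GB, params.K))
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = np.where(GA > 0, b / GA, 0.0)
        pB = np.where(GB > 0, b / GB, 0.0)
    G = (params.fA - 1) * (params.fB - 1) * pA * pB
    if G.max() < 1.0 or G.min() > 1.0:
        return []
    out = []
    for c in measure.find_contours(G, 1.0):
        ca = np.interp(c[:, 0], np.arange(len(grid)), grid)
        cb = np.interp(c[:, 1], np.arange(len(grid)), grid)
        out.append(np.column_stack([ca, cb]))
    return out


def stoichiometric_line(params: TheoryParameters) -> float:
    """Slope of the stoichiometric ray cB = slope * cA on which the site
    densities match (GammaA = GammaB): slope = (fA/NA) (NB/fB)."""
    return (params.fA / params.NA) * (params.NB / params.fB)


def athermal_limit_diagram(
    params: TheoryParameters,
    K_sequence=(1e-6, 1e-8, 1e-10),
    rel_tol: float = 5e-3,
    **binodal_kwargs,
) -> TheoreticalPhaseDiagram:
    """The K -> 0 (infinite binding strength) limit of the binodal.

    Binodals are constructed at a decreasing sequence of K values; the limit
    is accepted when the dilute/dense branches of the last two differ by
    less than ``rel_tol`` (relative, per matched tie line).  Raises when the
    sequence has not converged.
    """
    prev = None
    for K in K_sequence:
        d = construct_binodal(
            TheoryParameters(NA=params.NA, NB=params.NB, fA=params.fA,
                             fB=params.fB, K=K, vex=params.vex),
            **binodal_kwargs)
        if prev is not None and prev.has_coexistence and d.has_coexistence:
            if _branch_displacement(prev, d) < rel_tol:
                return d
        prev = d
    if prev is not None and prev.has_coexistence:
        raise RuntimeError(
            "athermal binodal did not converge across the K sequence")
    return prev if prev is not None else TheoreticalPhaseDiagram(params=params)


def _point_polyline_distance(p: np.ndarray, poly: np.ndarray):
    """(distance, interior) from point ``p`` to the piecewise-linear curve.

    ``interior`` is False when the nearest projection clamps to one of the
    two termini of the whole polyline, i.e. ``p`` lies beyond its coverage.
    """
    if len(poly) == 1:
        return float(np.linalg.norm(p - poly[0])), False
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    tpar = np.clip(((p - a) * ab).sum(axis=1) / np.maximum(denom, 1e-300), 0, 1)
    proj = a + tpar[:, None] * ab
    dist = np.linalg.norm(proj - p, axis=1)
    k = int(np.argmin(dist))
    interior = not ((k == 0 and tpar[0] == 0.0)
                    or (k == len(tpar) - 1 and tpar[-1] == 1.0))
    return float(dist[k]), interior


def _branch_displacement(d1: TheoreticalPhaseDiagram,
                         d2: TheoreticalPhaseDiagram) -> float:
    """Max relative displacement between the binodal branches of two
    diagrams, measured point-to-polyline over the branch region both
    families cover; a different tie-line sampling of the same loop then
    does not register as displacement."""
    dists = []
    total = 0
    for attr in ("dilute", "dense"):
        p1 = np.asarray([getattr(tl, attr) for tl in d1.tie_lines])
        p2 = np.asarray([getattr(tl, attr) for tl in d2.tie_lines])
        if len(p1) == 0 or len(p2) == 0:
            return np.inf
        for p in p1:
            total += 1
            d, interior = _point_polyline_distance(p, p2)
            if not interior:
                continue
            scale = max(np.linalg.norm(p), 1e-12)
            dists.append(d / scale)
    if len(dists) < total // 2:
        return np.inf  # families barely overlap; not comparable
    # upper-decile displacement: the extreme tail reflects differences in
    # how far around the loop each tie family reaches, not branch motion
    return float(np.quantile(dists, 0.9))
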