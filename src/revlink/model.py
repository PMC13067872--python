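"""Reduced units, interaction potentials, and model-parameter calculators.

The Hamiltonian of the model consists of

* a purely repulsive Weeks-Chandler-Andersen (WCA) potential between all
  non-exempt monomer pairs (good-solvent conditions),
* a short-range cosine attraction of depth 2*eps_sp between crosslinkable
  A- and B-monomers (the reversible crosslink),
* harmonic bonds between chain neighbours, and
* a harmonic bending potential on consecutive bond angles.

Two derived scalar parameters characterise the thermodynamics of a single
crosslink and of a single monomer: the dissociation constant K (the inverse
configurational bond volume of the binding potential) and the
excluded-volume parameter v_ex (the second virial coefficient of the WCA
potential).  Both are computed by adaptive quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad

__all__ = [
    "WCA_CUTOFF",
    "ModelParameters",
    "SystemTopology",
    "Concentrations",
    "wca_energy",
    "wca_force",
    "binding_energy",
    "binding_force",
    "bond_energy",
    "angle_energy",
    "dissociation_constant",
    "excluded_volume_parameter",
    "concentrations_from_counts",
    "default_a_positions",
]

#: Minimum of the Lennard-Jones potential; the WCA cutoff, in units of sigma.
WCA_CUTOFF: float = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ModelParameters:
    """All reduced-unit constants of the Hamiltonian and the integrator.

    Lengths are in the monomer diameter sigma, energies in kBT, masses in the
    monomer mass m; the time unit t0 = sigma*sqrt(m/kBT) is derived and not
    stored.  ``dt`` and ``gamma`` are not dictated by the model itself; the
    defaults (dt=0.005 t0, gamma=1 m/t0) are stable for the stiffest default
    interaction (kb=30 kBT/sigma^2) and are freely configurable.
    """

    sigma: float = 1.0
    kBT: float = 1.0
    mass: float = 1.0
    kb: float = 30.0          # bond spring constant [kBT/sigma^2]
    r0: float = WCA_CUTOFF    # equilibrium bond length [sigma]
    ka: float = 5.0           # bending constant [kBT]
    eps_wca: float = 1.0      # WCA strength [kBT]
    eps_sp: float = 6.0       # specific-binding strength [kBT]
    r_bind: float = 0.5       # binding cutoff [sigma]
    dt: float = 0.005         # integration step [t0]
    gamma: float = 1.0        # Langevin friction [m/t0]
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma", "kBT", "mass", "kb", "r0", "ka", "r_bind", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("eps_wca", "eps_sp", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def t0(self) -> float:
        """Intrinsic time unit sigma*sqrt(m/kBT)."""
        return self.sigma * math.sqrt(self.mass / self.kBT)

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


def default_a_positions(NA: int) -> list[int]:
    """Crosslinker placement on an A-chain: the two ends and the middle.

    Defined for odd NA (the middle monomer is unique).  For even NA the
    placement is ambiguous and must be supplied explicitly.
    """
    if NA < 3:
        raise ValueError("A-chains need at least 3 monomers for fA=3 placement")
    if NA % 2 == 0:
        raise ValueError(
            "default crosslinker placement (ends + middle) requires odd NA; "
            "pass a_positions explicitly for even NA"
        )
    return [0, NA // 2, NA - 1]


@dataclass(frozen=True)
class SystemTopology:
    """Chain species, lengths, crosslinker positions, chain counts and box.

    ``a_positions`` are 0-based monomer indices on each A-chain carrying a
    crosslinkable unit; ``b_pattern`` is the binary crosslinker sequence of
    the B-chains (1 = crosslinkable).  All A-chains are identical, as are
    all B-chains.
    """

    NA: int
    NB: int
    a_positions: tuple[int, ...]
    b_pattern: tuple[int, ...]
    nA: int
    nB: int
    box: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.NA < 1 or self.NB < 1:
            raise ValueError("chain lengths must be >= 1")
        if self.nA < 0 or self.nB < 0:
            raise ValueError("chain counts must be >= 0")
        if len(self.b_pattern) != self.NB:
            raise ValueError("b_pattern length must equal NB")
        if any(t not in (0, 1) for t in self.b_pattern):
            raise ValueError("b_pattern entries must be 0 or 1")
        if any(not 0 <= i < self.NA for i in self.a_positions):
            raise ValueError("a_positions out of range")
        if len(set(self.a_positions)) != len(self.a_positions):
            raise ValueError("a_positions must be distinct")
        if any(L <= 0 for L in self.box):
            raise ValueError("box lengths must be positive")

    @property
    def fA(self) -> int:
        return len(self.a_positions)

    @property
    def fB(self) -> int:
        return int(sum(self.b_pattern))

    @property
    def n_monomers(self) -> int:
        return self.nA * self.NA + self.nB * self.NB

    @property
    def volume(self) -> float:
        Lx, Ly, Lz = self.box
        return Lx * Ly * Lz

    @classmethod
    def preset(
        cls,
        NA: int = 7,
        nA: int = 0,
        nB: int = 0,
        box: tuple[float, float, float] = (30.0, 30.0, 30.0),
        NB: int = 65,
        b_pattern: tuple[int, ...] | None = None,
        a_positions: tuple[int, ...] | None = None,
    ) -> "SystemTopology":
        """Standard topology: fA=3 A-chains (ends + middle) and NB=65
        B-chains with fB=32 crosslinkers distributed evenly (alternating)."""
        if a_positions is None:
            a_positions = tuple(default_a_positions(NA))
        if b_pattern is None:
            pat = [0] * NB
            for i in range(0, min(2 * 32, NB), 2):
                pat[i] = 1
            b_pattern = tuple(pat)
        return cls(NA=NA, NB=NB, a_positions=tuple(a_positions),
                   b_pattern=tuple(b_pattern), nA=nA, nB=nB, box=tuple(box))


@dataclass(frozen=True)
class Concentrations:
    """Monomer number densities of the two species [sigma^-3]."""

    cA: float
    cB: float

    def __post_init__(self) -> None:
        if self.cA < 0 or self.cB < 0:
            raise ValueError("concentrations must be non-negative")


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

def wca_energy(r, eps: float = 1.0):
    """WCA energy 4*eps*[(sigma/r)^12 - (sigma/r)^6 + 1/4] for r < 2^(1/6).

    Vectorised over ``r``; raises for non-positive separations.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("WCA potential requires r > 0")
    inv6 = np.where(r < WCA_CUTOFF, (1.0 / r) ** 6, 0.0)
    u = np.where(r < WCA_CUTOFF, 4.0 * eps * (inv6 * inv6 - inv6 + 0.25), 0.0)
    return u if u.ndim else float(u)


def wca_force(r, eps: float = 1.0):
    """Magnitude of the radial WCA force, -dU/dr (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("WCA potential requires r > 0")
    inv = 1.0 / r
    inv6 = inv ** 6
    f = np.where(r < WCA_CUTOFF, 4.0 * eps * (12.0 * inv6 * inv6 - 6.0 * inv6) * inv, 0.0)
    return f if f.ndim else float(f)


def binding_energy(r, eps_sp: float = 6.0):
    """Crosslink attraction -eps_sp*[cos(2*pi*r) + 1] for r < 0.5 sigma."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("binding potential requires r >= 0")
    u = np.where(r < 0.5, -eps_sp * (np.cos(2.0 * np.pi * r) + 1.0), 0.0)
    return u if u.ndim else float(u)


def binding_force(r, eps_sp: float = 6.0):
    """Radial binding force -dU/dr; negative (attractive) for 0 < r < 0.5."""
    r = np.asarray(r, dtype=float)
    f = np.where(r < 0.5, -eps_sp * 2.0 * np.pi * np.sin(2.0 * np.pi * r), 0.0)
    return f if f.ndim else float(f)


def bond_energy(r, kb: float = 30.0, r0: float = WCA_CUTOFF):
    """Harmonic bond (kb/2)*(r - r0)^2."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be positive")
    u = 0.5 * kb * (r - r0) ** 2
    return u if u.ndim else float(u)


def angle_energy(theta, ka: float = 5.0):
    """Harmonic bending (ka/2)*(theta - pi)^2 on consecutive bonds."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > np.pi)):
        raise ValueError("bond angle must lie in [0, pi]")
    u = 0.5 * ka * (theta - np.pi) ** 2
    return u if u.ndim else float(u)


# ---------------------------------------------------------------------------
# derived scalar parameters
# ---------------------------------------------------------------------------

def bond_volume(eps_sp: float = 6.0) -> float:
    """Configurational bond volume of the binding potential [sigma^3].

    v_b = int_0^{1/2} exp(-beta U_bind(r)) 4 pi r^2 dr; the Boltzmann weight
    of the bound region.  At eps_sp = 0 this is the volume of a sphere of
    radius 0.5 sigma.
    """
    if eps_sp < 0:
        raise ValueError("eps_sp must be non-negative")
    val, err = quad(
        lambda r: math.exp(eps_sp * (math.cos(2.0 * math.pi * r) + 1.0))
        * 4.0 * math.pi * r * r,
        0.0, 0.5, epsrel=1e-10, limit=200,
    )
    if not math.isfinite(val) or (val > 0 and err / val > 1e-8):
        raise RuntimeError("bond-volume quadrature did not converge")
    return val


def dissociation_constant(eps_sp: float = 6.0) -> float:
    """Dissociation constant K = 1/v_b of a single crosslink [sigma^-3].

    For the default binding strength eps_sp = 6 kBT this evaluates to
    K = 0.001257 sigma^-3.
    """
    return 1.0 / bond_volume(eps_sp)


def excluded_volume_parameter(eps_wca: float = 1.0) -> float:
    """Second virial coefficient of the WCA potential [sigma^3].

    v_ex = 2 pi int_0^{2^(1/6)} (1 - exp(-beta U_WCA(r))) r^2 dr.
    Evaluates to 2.2 sigma^3 at eps = 1 kBT and approaches the hard-sphere
    value (2 pi / 3) * 2^(1/2) ~ 2.962 sigma^3 as eps -> infinity.
    """
    if eps_wca < 0:
        raise ValueError("eps_wca must be non-negative")
    if eps_wca == 0:
        return 0.0

    def integrand(r: float) -> float:
        inv6 = (1.0 / r) ** 6
        u = 4.0 * eps_wca * (inv6 * inv6 - inv6 + 0.25)
        # exp(-u) underflows harmlessly to 0 deep in the core
        return (1.0 - math.exp(-min(u, 700.0))) * r * r

    val, _ = quad(integrand, 0.0, WCA_CUTOFF, epsrel=1e-10, limit=200)
    return 2.0 * math.pi * val


def concentrations_from_counts(topology: SystemTopology) -> Concentrations:
    """Monomer number densities cX = nX*NX/V from chain counts and box."""
    V = topology.volume
    if V <= 0:
        raise ValueError("box volume must be positive")
    return Concentrations(
        cA=topology.nA * topology.NA / V,
        cB=topology.nB * topology.NB / V,
    )
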