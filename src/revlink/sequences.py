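"""Crosslinker sequences and the blockiness metric.

A B-chain of length N carries f crosslinkable monomers; their arrangement is
a binary sequence S = (tau_1, ..., tau_N).  Blockiness is quantified by the
inverse-distance pair sum

    I[S] = sum_{i<j} tau_i tau_j / (j - i),

normalised between a maximally even (alternating-style) reference sequence
and the single contiguous block (diblock):

    I_block = (I[S] - I_min) / (I_max - I_min).

The normalisation follows the "sequence charge decoration" idea used for
charge patterns of intrinsically disordered proteins, applied here to
crosslinker patterns.  For the standard B-chain (N=65, f=32) the reference
values are I_min = 48.94 (crosslinkers at every second position) and
I_max = 97.87 (diblock).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CrosslinkSequence",
    "BlockinessReport",
    "sequence_I",
    "family_extremes",
    "blockiness",
    "generate_regular",
    "generate_irregular",
    "alternating_sequence",
    "diblock_sequence",
]


@dataclass(frozen=True)
class CrosslinkSequence:
    """Binary crosslinker pattern tau over a chain (1 = crosslinkable)."""

    tau: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if any(t not in (0, 1) for t in self.tau):
            raise ValueError("tau entries must be 0 or 1")

    @property
    def N(self) -> int:
        return len(self.tau)

    @property
    def f(self) -> int:
        return int(sum(self.tau))

    @property
    def positions(self) -> np.ndarray:
        """0-based indices of crosslinkable monomers."""
        return np.flatnonzero(np.asarray(self.tau))

    @classmethod
    def from_positions(cls, N: int, positions, label: str = "") -> "CrosslinkSequence":
        tau = [0] * N
        for p in positions:
            if not 0 <= p < N:
                raise ValueError(f"position {p} outside chain of length {N}")
            tau[p] = 1
        return cls(tau=tuple(tau), label=label)

    @classmethod
    def from_string(cls, s: str, label: str = "") -> "CrosslinkSequence":
        return cls(tau=tuple(int(c) for c in s.strip()), label=label)

    def __str__(self) -> str:
        return "".join(str(t) for t in self.tau)


@dataclass(frozen=True)
class BlockinessReport:
    """Raw pair sum I[S], family normalisers, and the normalised I_block."""

    I_raw: float
    I_min: float
    I_max: float
    I_block: float


def sequence_I(seq: CrosslinkSequence) -> float:
    """Inverse-distance pair sum I[S] = sum_{i<j} tau_i tau_j / (j-i).

    Exact double sum over crosslinkable positions (index differences are the
    same for 0- and 1-based labelling).
    """
    pos = seq.positions.astype(float)
    if len(pos) < 2:
        return 0.0
    diff = pos[None, :] - pos[:, None]
    iu = np.triu_indices(len(pos), k=1)
    return float(np.sum(1.0 / diff[iu]))


def alternating_sequence(N: int, f: int, label: str = "alternating") -> CrosslinkSequence:
    """Maximally even placement: f crosslinkers at every second position.

    Requires 2*f - 1 <= N so that spacing 2 fits; this is the reference
    sequence defining I_min for the (N, f) family.
    """
    if f < 1:
        raise ValueError("need at least one crosslinker")
    if 2 * f - 1 > N:
        raise ValueError(f"alternating placement of {f} sites needs N >= {2*f-1}")
    return CrosslinkSequence.from_positions(N, range(0, 2 * f, 2), label=label)


def diblock_sequence(N: int, f: int, label: str = "diblock") -> CrosslinkSequence:
    """Single contiguous block of f crosslinkers at the chain start."""
    if not 1 <= f <= N:
        raise ValueError("need 1 <= f <= N")
    return CrosslinkSequence.from_positions(N, range(f), label=label)


def family_extremes(N: int, f: int) -> tuple[float, float]:
    """(I_min, I_max) of the (N, f) sequence family.

    I_min is the alternating reference, I_max the diblock; both are computed,
    not tabulated, so arbitrary (N, f) are supported.  For (65, 32) this
    reproduces (48.94, 97.87).
    """
    if f < 1:
        raise ValueError("family requires f >= 1 crosslinkers")
    if f > N:
        raise ValueError("f cannot exceed N")
    if f == 1:
        warnings.warn("degenerate family f=1: no pairs, I_min = I_max = 0")
        return (0.0, 0.0)
    return (sequence_I(alternating_sequence(N, f)), sequence_I(diblock_sequence(N, f)))


def blockiness(
    seq: CrosslinkSequence,
    extremes: tuple[float, float] | None = None,
) -> BlockinessReport:
    """Normalised blockiness I_block = (I[S] - I_min)/(I_max - I_min).

    ``extremes`` defaults to :func:`family_extremes` of the sequence's own
    (N, f).  Values outside [0, 1] are reported as-is with a warning: the
    alternating reference is not guaranteed to be the global minimum over
    all sequences of the family.
    """
    I_raw = sequence_I(seq)
    I_min, I_max = extremes if extremes is not None else family_extremes(seq.N, seq.f)
    if I_max <= I_min:
        raise ValueError("degenerate family: I_max must exceed I_min")
    I_block = (I_raw - I_min) / (I_max - I_min)
    if not 0.0 <= I_block <= 1.0:
        warnings.warn(
            f"I_block = {I_block:.4f} outside [0, 1]: sequence lies outside "
            "the alternating/diblock normalisation bracket"
        )
    return BlockinessReport(I_raw=I_raw, I_min=I_min, I_max=I_max, I_block=I_block)


def generate_regular(N: int, f: int, block_size: int) -> CrosslinkSequence:
    """Regular sequence: f/block_size equal crosslinker blocks spaced evenly.

    ``block_size`` must divide f.  block_size=1 recovers the alternating-style
    family minimum, block_size=f the diblock.
    """
    if block_size < 1 or f % block_size != 0:
        raise ValueError("block_size must divide f")
    n_blocks = f // block_size
    if n_blocks == 1:
        return diblock_sequence(N, f, label=f"regular-b{block_size}")
    # spread block start positions evenly over the available span
    span = N - block_size
    if span < 0 or (N - f) < (n_blocks - 1):
        raise ValueError("blocks do not fit in the chain with gaps")
    starts = np.round(np.linspace(0, span, n_blocks)).astype(int)
    positions: list[int] = []
    for s in starts:
        positions.extend(range(s, s + block_size))
    if len(set(positions)) != f:
        raise ValueError("evenly spaced blocks overlap; reduce block_size or f")
    return CrosslinkSequence.from_positions(N, positions, label=f"regular-b{block_size}")


def generate_irregular(
    N: int,
    f: int,
    target_Iblock: float,
    rng: np.random.Generator,
    tol: float = 0.01,
    max_iter: int = 20000,
) -> CrosslinkSequence:
    """Irregular sequence with a prescribed blockiness, by pair-swap annealing.

    Starting from a random placement of f crosslinkers, single-site moves are
    accepted whenever they reduce |I_block - target|; stops when the target is
    met within ``tol``.  Raises if the target remains unreachable after
    ``max_iter`` moves, reporting the closest achieved value.
    """
    if not 0.0 <= target_Iblock <= 1.0:
        raise ValueError("target_Iblock must lie in [0, 1]")
    extremes = family_extremes(N, f)
    I_min, I_max = extremes
    if I_max <= I_min:
        raise ValueError("degenerate family")

    tau = np.zeros(N, dtype=int)
    tau[rng.choice(N, size=f, replace=False)] = 1

    def score(t: np.ndarray) -> float:
        seq = CrosslinkSequence(tau=tuple(int(x) for x in t))
        return (sequence_I(seq) - I_min) / (I_max - I_min)

    current = score(tau)
    best = current
    for _ in range(max_iter):
        if abs(current - target_Iblock) < tol:
            break
        ones = np.flatnonzero(tau)
        zeros = np.flatnonzero(tau == 0)
        i = ones[rng.integers(len(ones))]
        j = zeros[rng.integers(len(zeros))]
        tau[i], tau[j] = 0, 1
        trial = score(tau)
        if abs(trial - target_Iblock) <= abs(current - target_Iblock):
            current = trial
            best = min(best, current, key=lambda x: abs(x - target_Iblock))
        else:
            tau[i], tau[j] = 1, 0
    else:
        raise ValueError(
            f"target I_block={target_Iblock} unreachable within tolerance; "
            f"closest achieved {best:.4f}"
        )
    return CrosslinkSequence(
        tau=tuple(int(x) for x in tau),
        label=f"irregular-I{target_Iblock:.2f}",
    )
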