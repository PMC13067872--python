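"""Named presets for the standard study conditions.

The reference mixture: A-chains of length NA in {5, 7, 9, 11, 13, 23} with
fA = 3 crosslinkers at the two ends and the middle; B-chains of length
NB = 65 with fB = 32 crosslinkers placed evenly (every second monomer);
kb = 30 kBT/sigma^2, ka = 5 kBT, eps = 1 kBT, eps_sp = 6 kBT.  Slab runs
start from a 30^3 cube extended to Ly = 300.
"""

from __future__ import annotations

from revlink.model import ModelParameters, SystemTopology
from revlink.simulate import SlabProtocolSpec

__all__ = ["default_params", "mixture_topology", "preset"]


def default_params() -> ModelParameters:
    return ModelParameters()


def mixture_topology(
    NA: int = 7,
    cA: float = 0.02,
    cB: float = 0.01,
    box: tuple[float, float, float] = (30.0, 30.0, 30.0),
    NB: int = 65,
) -> SystemTopology:
    """Topology with chain counts chosen to realise (cA, cB) in ``box``.

    Counts are rounded to whole chains, so the realised concentrations
    (nX*NX/V) differ from the request by at most one chain.
    """
    V = box[0] * box[1] * box[2]
    nA = max(0, int(round(cA * V / NA)))
    nB = max(0, int(round(cB * V / NB)))
    return SystemTopology.preset(NA=NA, nA=nA, nB=nB, box=box, NB=NB)


def preset(name: str):
    """Resolve a named preset to (params, topology, slab_spec | None)."""
    params = default_params()
    if name.startswith("paper-NA") and name.endswith("-slab"):
        NA = int(name[len("paper-NA"):-len("-slab")])
        topo = mixture_topology(NA=NA, box=(30.0, 30.0, 30.0))
        return params, topo, SlabProtocolSpec()
    if name.startswith("reduced-NA") and name.endswith("-slab"):
        NA = int(name[len("reduced-NA"):-len("-slab")])
        spec = SlabProtocolSpec.reduced()
        L0 = spec.initial_box
        topo = mixture_topology(NA=NA, cA=0.045, cB=0.035, box=(L0, L0, L0))
        return params, topo, spec
    if name == "single-B-chain":
        topo = SystemTopology.preset(NA=7, nA=0, nB=1, box=(80.0, 80.0, 80.0))
        return params, topo, None
    raise KeyError(
        f"unknown preset {name!r}; known: paper-NA<len>-slab, "
        "reduced-NA<len>-slab, single-B-chain"
    )
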