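# revlink

Reversible-crosslink-driven liquid–liquid phase separation: a
coarse-grained Langevin simulator, trajectory analysis, and mean-field
Semenov–Rubinstein theory for mixtures of two bead–spring polymer species
whose designated monomers form strong but transient one-to-one bonds.

## The problem

Classically, polymer solutions demix because solvent quality drops or
because associative (e.g. electrostatic) interactions drive coacervation.
`revlink` implements a third, purely connectivity-driven mechanism:
species A and B live in implicit *good* solvent (all non-bonded
interactions are repulsive WCA), and only designated "crosslinkable"
monomers attract each other, forming saturating one-to-one reversible
bonds.  The combinatorial entropy of rearranging these crosslinks alone
can condense the mixture into ultra-dilute, water-rich droplets — a model
for highly permeable biomolecular condensates (RNA–protein mixtures) and
programmable synthetic gels.  The package is for polymer/biophysics
researchers who want to simulate this mechanism, analyse its phase
behaviour, or compare against the mean-field theory.

## Model in brief

Bead–spring chains (harmonic bonds, k_b = 30 kBT/σ², r₀ = 2^{1/6}σ;
harmonic bending, k_a = 5 kBT; WCA with ε = 1 kBT) in reduced units.
Crosslinkable A/B monomer pairs interact through
βU = −ε_sp[cos(2πr/σ)+1] for r < σ/2 with ε_sp = 6 kBT, giving a
dissociation constant

    K = [∫₀^{σ/2} e^{−βU(r)} 4πr² dr]⁻¹ = 0.001257 σ⁻³.

Once a pair has bonded, third parties see plain WCA from its members
(one bond per site).  The mean-field free-energy density

    f = (c_A/N_A)[ln(c_A/N_A) − 1] + (c_B/N_B)[ln(c_B/N_B) − 1]
      + (v_ex/2)(c_A + c_B)² + Γ_A ln X_A + Γ_B ln X_B + b

(Γ_X crosslinkable-site densities, b the mass-action bond density, X_X
free-site fractions, v_ex the effective repulsion) predicts closed-loop
coexistence with reentrant phase separation and a reentrant
Flory–Stockmayer sol–gel line.  See `docs/methods.md` for the full
formulation and numerical choices.

## Worked example

Score the reference crosslinker sequences, get the theory's phase
diagram, and run a short bulk simulation:

```python
import numpy as np
from revlink.sequences import diblock_sequence, alternating_sequence, sequence_I
from revlink.model import dissociation_constant, excluded_volume_parameter
from revlink.theory import TheoryParameters, construct_binodal

print(sequence_I(diblock_sequence(65, 32)))      # 97.87184625396885
print(sequence_I(alternating_sequence(65, 32)))  # 48.93592312698443
print(dissociation_constant(6.0))                # 0.00125730960757897
print(excluded_volume_parameter(1.0))            # 2.204723155300258

diagram = construct_binodal(TheoryParameters())  # NA=7, K=0.001257, vex=1.73
print(diagram.closed_loop, len(diagram.tie_lines))  # True 57
tl = diagram.tie_lines[48]
print(np.round(tl.dilute, 5), np.round(tl.dense, 5))
# [0.00021 0.00515] [0.0104 0.0389]
```

The last line is one tie line of the closed-loop binodal: a dilute phase
at total monomer density ≈ 0.005 σ⁻³ coexisting with a "dense" phase at
only ≈ 0.049 σ⁻³ — a condensate that is ~97% solvent by volume, which is
the point of the mechanism.

Simulation with live crosslinking, e.g. a small mixture:

```python
from revlink.model import ModelParameters, SystemTopology
from revlink.simulate import run_bulk_simulation
from revlink.analysis import connectivity_and_percolation

params = ModelParameters()                    # eps_sp = 6 kBT preset
topo = SystemTopology.preset(NA=7, nA=60, nB=8, box=(18., 18., 18.))
traj = run_bulk_simulation(params, topo, duration=200.0, seed=1,
                           frame_interval=50.0)
print(len(traj.frames[-1].pairs))             # 135 crosslinks
print(connectivity_and_percolation(traj.frames[-1], topo).spanning)  # True
```

A CLI mirrors the library:

```bash
revlink sequence score 11111111111111111111111111111111000000000000000000000000000000000
revlink theory binodal --na 7 --out out/
revlink simulate slab --preset reduced-NA7-slab --seed 1 --out out/
revlink analyze profile out/trajectory --out out/
```

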