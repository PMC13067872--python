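# Methods

## The model

`revlink` implements a minimal coarse-grained model of two bead-spring
polymer species A and B in implicit good solvent whose designated
"crosslinkable" monomers form strong but transient one-to-one bonds.  The
question the model isolates is whether reversible pairwise crosslinking
*alone* — with purely repulsive non-bonded interactions everywhere else —
can drive liquid–liquid phase separation, and what the resulting phase
behaviour looks like.

All quantities are in reduced units: lengths in the monomer diameter σ,
energies in kBT, masses in the monomer mass m, times in t0 = σ√(m/kBT).

Interactions:

* **WCA repulsion** between all non-exempt monomer pairs:
  βU = 4ε[(σ/r)¹² − (σ/r)⁶ + ¼] for r < 2^{1/6}σ, zero beyond.  Default
  ε = 1 (good solvent).
* **Crosslink attraction** between crosslinkable A- and B-monomers:
  βU = −ε_sp[cos(2πr/σ) + 1] for r < σ/2, zero beyond; depth 2ε_sp at
  contact.  Default ε_sp = 6, corresponding to a dissociation constant
  K = 1/v_b = 0.001257 σ⁻³, where v_b = ∫₀^{σ/2} e^{−βU} 4πr² dr is the
  configurational bond volume.
* **Bonds**: harmonic, βU = (k_b/2)(r − r₀)², k_b = 30 kBT/σ²,
  r₀ = 2^{1/6}σ.
* **Bending**: harmonic in the angle between consecutive bonds,
  βU = (k_a/2)(θ − π)², k_a = 5 kBT, giving a persistence length of
  5–6 σ.

Saturation (one partner per site) is enforced by a dynamic registry:
a free-A/free-B crosslinker pair interacts through the attraction; the
moment the two come within the binding range r < σ/2 the pair is
*registered*, and any third crosslinker then sees plain WCA repulsion
from either member.  Registered pairs whose separation exceeds σ/2
break and both sites become free again.  When several candidate pairs
compete in one step, they are accepted greedily in ascending distance
order (exact ties broken by lowest monomer-id pair) subject to the
one-to-one constraint.  Setting ε_sp = 0 switches the entire binding
machinery off; trajectories are then independent of it.

Reference architecture: A-chains of length N_A ∈ {5, 7, 9, 11, 13, 23}
with f_A = 3 crosslinkers at the two ends and the middle; B-chains of
length N_B = 65 with f_B = 32 crosslinkers, default arrangement every
second monomer.

### Non-bonded exclusions

Directly bonded neighbours interact through the harmonic bond only; they
are excluded from the WCA sum (the convention of the major MD engines'
default neighbour lists, and of the engine the reference parameter set was
tuned in).  This choice is observable: with bonded WCA included, the mean
bond length inflates from ≈1.18 σ to ≈1.24 σ and the persistence length
from ≈6 σ to ≈7 σ, outside the 5–6 σ range the parameter set is quoted to
produce.  A switch (`wca_bonded=True`) restores the alternative convention.

## Integrator

Langevin dynamics via the BAOAB splitting at kBT = 1, dt = 0.005 t0,
friction γ = 1 m/t0 (dt and γ are stability/efficiency choices, not model
parameters; γ = 0 reduces the scheme to velocity Verlet and is used in the
energy-conservation test).  The Ornstein–Uhlenbeck (thermostat) substep is
applied every 4th step with decay constants compensated for the longer
interval — plain velocity Verlet in between — which keeps the noise exactly
Gaussian while quartering its generation cost; the lumped friction interval
(0.02 t0) stays an order of magnitude below the stiffest oscillation period
of the model (~0.3 t0, the binding well).  Gaussian noise distributions
matter here: the bound-pair free energy is measurably biased by
variance-matched non-Gaussian noise, because BAOAB's configurational
sampling is exact for harmonic modes only with Gaussian increments.
Non-bonded pairs are iterated through a half Verlet list (cutoff
2^{1/6}σ + 0.4 σ skin) rebuilt from a cell grid whenever any particle has
moved more than half the skin.  Noise is pre-generated in chunks by
numpy's PCG64 generator, seeded once per segment, so a trajectory is a
deterministic function of its seed.

**Force cap.**  The registry's WCA switch can place a third crosslinker
transiently *inside* a WCA core (it approached under the attraction while
all parties were free; a competing pair then registered first).  The bare
WCA force there reaches 10⁴–10⁵ kBT/σ and would destabilise any practical
timestep.  All pair forces are therefore capped at 500 kBT/σ.  The cap
only modifies the force where βU_WCA ≳ 30 (r ≲ 0.82 σ), a region with
equilibrium Boltzmann weight < 10⁻¹³, so equilibrium observables are
unaffected; it merely bounds the rate at which the (physically intended)
expulsion of the intruder injects energy, which the thermostat then
absorbs.

**Initialisation.**  Chains are grown sequentially with random bond
orientations; placements closer than 0.9 σ to any placed monomer are
rejected.  In dense boxes the criterion relaxes stepwise to 0.8 σ
(residual soft contacts relax within a few steps under the capped
forces); an error is raised only when growth fails at the loosest
criterion after 10⁵ attempts, suggesting a larger box.

## Protocols

* **Bulk**: fixed periodic box, optional unsampled equilibration period,
  then production frames at a fixed interval.  Used for percolation
  scans and single-chain statistics.
* **Slab**: pre-run in a cubic box, extension of one axis (coordinates
  kept, vacuum appended; chains are unwrapped through their image
  counters so none is cut), equilibration, then production emitting a
  fixed frame count.  Full-scale defaults follow the reference protocol
  (30³ → L_y = 300, 5×10⁴ t0 pre-run, 5×10⁵ t0 equilibration and
  production, 100 frames); a `reduced()` constructor scales the geometry
  and durations down for desk-scale work.

## Analysis

* **Density profiles** along the slab axis, per species and monomer
  class, with per-frame re-centering of the largest bond-network
  cluster's centre of mass (circular mean) to keep interfaces sharp.
* **Coexistence densities** from a two-interface tanh fit of the total
  profile.  Plateau densities are measured from bins ≥ 3 fitted widths
  away from either interface (the tanh tail at 2w still carries ~2% of
  the contrast); branch standard errors combine the bin-average error
  with the fitted plateau parameter's uncertainty, because the bin
  selection itself depends on the fitted interfaces.  A result is
  "no coexistence" when the fit fails or the plateau contrast is below
  3 combined standard errors.
* **Block-distribution analysis** as an independent route: densities of
  cubic sub-blocks pooled over frames; a bimodal distribution (two peaks
  separated by a valley deeper than half the lower peak) signals
  coexistence, with branch densities from blocks near each mode (blocks
  straddling an interface populate the valley and are excluded).  The
  method needs ≳ tens of particles per block to beat Poisson
  discreteness; for very dilute systems the profile route is the
  reliable one.
* **Percolation**: graph nodes are monomers, edges are backbone bonds
  plus registered crosslinks.  Union-find tracks an integer image offset
  per node; an edge that closes a cycle with a nonzero net offset along
  axis k marks its cluster as spanning k (a continuous bond path
  connects a particle to its own periodic image — note this requires a
  *cycle*; a linear chain touching its image is not percolating).
  Chain-level clusters contract backbones.  Tested against a brute-force
  3×3×3 open-boundary replication oracle.
* **Motifs**: per A-chain — unbound / singly bound / loop (≥2 bonds, one
  B-chain) / bridge (≥2 bonds, ≥2 distinct B-chains; mixed cases with 3
  bonds on 2 chains count as bridges).
* **S(k)** over box-commensurate wavevectors, spherically binned; **g(r)**
  by minimum-image pair histogram against the ideal-gas shell count.
* **Chain statistics**: Rg and Ree from unwrapped coordinates;
  persistence length from an exponential fit of the bond-vector
  correlation over its initial decay (correlations > 0.2); end-to-end
  decorrelation time as the integrated autocorrelation up to the first
  zero crossing, which also deflates the effective sample count behind
  the reported Rg² standard error; overlap concentration
  c* = N/((4/3)π⟨Rg²⟩^{3/2}).

## Mean-field theory

The Semenov–Rubinstein-type free-energy density implemented is

    f = (c_A/N_A)[ln(c_A/N_A) − 1] + (c_B/N_B)[ln(c_B/N_B) − 1]
      + (v_ex/2)(c_A + c_B)² + Γ_A ln X_A + Γ_B ln X_B + b ,

with site densities Γ_X = f_X c_X/N_X, bond density b the root of the
mass-action law (Γ_A − b)(Γ_B − b) = K b (numerically stable quadratic
form, exact in both the K → 0 and K → ∞ limits), and free-site fractions
X_X = (Γ_X − b)/Γ_X.  The association term is the Wertheim
one-bond-per-site form Γ_X(ln X_X − X_X/2 + ½) summed over species and
rewritten with b.  Chemical potentials use the mass-action envelope
(∂f/∂b = 0), so μ_A = (1/N_A)ln(c_A/N_A) + v_ex(c_A + c_B) +
(f_A/N_A) ln X_A, and Π = c_A μ_A + c_B μ_B − f.  Without association the
free energy is strictly convex: every demixing the theory produces is
driven by the pairing term.

Two parameters beyond the topology: K (from the binding potential;
0.001257 σ⁻³ at ε_sp = 6) and the effective repulsion v_ex.  The bare
second virial coefficient of a free monomer gives v_ex = 2.2 σ³; the
default v_ex = 1.73 σ³ is the value that matches the simulated phase
boundaries (connected monomers repel effectively less).  v_ex is an input
parameter; no fit is performed here.

**Binodal construction** is two-stage: (1) f is sampled on a geometric
(c_A, c_B) grid and the lower convex envelope of the surface is taken;
envelope facet edges much longer than the local grid spacing seed tie
lines; (2) each seed is refined by Newton iteration (in log densities)
on μ_A, μ_B and Π equality, with a fourth equation pinning the tie-line
midpoint along the seed direction.  Residuals are verified < 10⁻⁸.
Critical points are reported as the midpoints of the extremal tie lines
of the refined family; the closed-loop flag requires the dense branch to
stay inside the sampled window.  For region queries (reentrance scans,
enclosure comparisons) the envelope itself is used directly: a sampled
composition is two-phase iff it is not a vertex of the lower hull.

**Percolation line**: Flory–Stockmayer gelation for the alternating
two-species network, (f_A − 1)(f_B − 1) p_A p_B = 1 with bound-site
fractions p_X = b/Γ_X.  This ignores loops and spatial correlations; the
simulated percolation threshold deviates from it quantitatively (the
mean-field line is the qualitative reference).

**Athermal limit** (ε_sp → ∞, K → 0): constructed numerically at a
decreasing K sequence (10⁻⁶, 10⁻⁸, 10⁻¹⁰ σ⁻³) rather than from a
hand-derived limiting form.  Convergence is accepted when the binodal
branches of successive diagrams differ by < 0.5% (upper-decile
point-to-polyline displacement over the branch region both tie-line
families cover; the extreme tail of that distribution measures how far
around the loop each family reached, not branch motion).  Only the
K-linear terms of f depend on K in this regime — they shift chemical
potentials by constants and cancel from all coexistence conditions —
so the limit is well defined.

## The synthetic-data generators

The deterministic fixtures (winding ring, bound dimer, ideal gas, simple
cubic lattice, tanh slab) exercise each analysis operator against known
answers: they provide exact percolation flags, S(k) = 1 and g(r) = 1
references, a Bragg peak at 2π/a, and Poisson-sampled two-plateau
profiles with known coexistence densities and interface width.  They are
sampling constructs, not simulations: the tanh slab has no chain
connectivity, no crosslinks and no interfacial fluctuations, so passing
its tests validates the *estimators* (fits, histograms, error bars), not
the physics of interface formation — that is what the scaled-down slab
simulation covers qualitatively.

## Desk-scale problem sizes

The full-scale study conditions (boxes up to 30×300×30 σ³, 10⁶ t0 per
run, 4–10 replicas per state point) are supported by the code but the
package's validation suite runs reduced versions, chosen as the smallest
systems in which each phenomenon is still expressed:

* single B-chain statistics: one N=65 chain, 2.5×10⁵ t0 production
  (≈10³ effective samples given the ≈1.5×10³ t0 end-to-end
  decorrelation time);
* dimer/partition-function link: two crosslinkable monomers in a 20³ box,
  8 independent replicas of 1.2×10⁵ t0;
* slab coexistence: 16³ cube (≈600 monomers) extended to 16×80×16,
  8×10³ t0 equilibration, 4×10³ t0 production;
* percolation reentrance: a 20³ box with one B-chain and a c_A sweep
  spanning the bridge-rich window into the A-excess regime (the
  Flory-Stockmayer exit concentration is unaffordable at desk scale; the
  simulated gel dissolves at far lower A excess, consistent with the
  mean-field line being only qualitative).

Finite-size effects at these sizes shift quantitative thresholds; the
reduced runs are asserted qualitatively (presence of two plateaus,
rise-and-fall of the percolation probability), never against the
full-scale numbers.

## Known limitations

* No hydrodynamics, electrostatics or explicit solvent (deliberate —
  the model isolates connectivity-driven condensation).
* Binding kinetics (lifetimes, on-rates) depend on the friction γ and
  the deterministic greedy matcher; only equilibrium properties are
  validated.
* The mean-field theory omits sequence information and spatial
  correlations; its dilute-branch predictions below the B-chain overlap
  concentration c* ≈ 0.012 σ⁻³ are extrapolations.
* The block-distribution coexistence route degrades for blocks holding
  few particles (Poisson discreteness), and the tanh-fit route assumes a
  single slab; neither handles micellar/microstructured morphologies.
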