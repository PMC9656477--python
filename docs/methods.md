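# Methods

## Model and propagation

All particles are hard spheres in an implicit solvent at T = 293 K
(viscosity 1.002×10⁻³ Pa·s, water). Monomeric units and crosslinkers have
diameter 0.65 nm; drug molecules 0.75–1.75 nm. Internal units are nm, ns
and kBT; the spring constant kₑ = 0.4 N/m converts to 98.88 kBT/nm² at
293 K (kB = 1.380649×10⁻²³ J/K), and free diffusion coefficients come from
Einstein–Stokes (0.66 nm²/ns for a network bead, 0.57→0.24 nm²/ns for
0.75→1.75 nm drugs).

One time step (Δt = 3 ps) visits every mobile bead once, in a fresh random
permutation. A bead's trial displacement is √(2D₀Δt)·N(0,1) per Cartesian
component, plus the deterministic drift D₀FΔt/kBT for network beads in
flexible mode, where F accumulates the Hookean bond forces −kₑ(r−r₀)r̂
evaluated once from the start-of-step configuration (at Δt = 3 ps the
force change within a step is negligible, and the cost stays O(bonds)).
A trial is accepted iff it creates no overlap with any other bead in the
current, partially updated configuration; sequential single-particle
trials avoid the unresolvable simultaneous-overlap states a synchronous
update would create. The rejection rule is unqualified — bonded pairs are
**not** exempt. Because the bond rest length r₀ equals the contact
distance, bond lengths therefore sample the Boltzmann distribution of the
harmonic bond restricted to non-overlapping separations r ≥ r₀ (mean
≈ r₀ + 0.08 nm); the engine test suite checks this against the 1-D
restricted-Boltzmann integral. We verified the alternative (exempting
bonded pairs, which lets bonds compress below contact) collapses the
reference gel to a volume fraction ~0.10 and a crosslinker spacing of
1.68 nm, far denser than the gel the release experiments are meant to
probe, so the unqualified rule is used throughout.

The simulation box (side 10 µm, reflecting walls) is irrelevant at release
time scales; reflection merely avoids periodic-image bookkeeping. Overlap
detection uses a linked-cell grid whose edge equals the largest network
bead diameter, with a per-bead integer scan radius so larger solutes
search as many neighbouring cells as their contact distance requires; the
grid is kept tight around the particles (cache-resident) and rebuilt
larger on the rare occasion a diffusing solute reaches its rim. An
all-pairs audit (`check_every`) can verify the no-overlap invariant at
every step. Per-step Gaussian displacements are drawn from a seeded numpy
PCG64 stream in batches; the visit permutation uses numba's seeded
generator; one seed therefore fixes a trajectory bit-exactly on a given
platform.

## Nanogel generation

The reference topology is 692 chains of 4 monomer beads joined by 404
crosslinkers (3172 network beads, 3460 bonds). Crosslinkers occupy the
sites of a diamond (tetrahedrally coordinated) lattice with
nearest-neighbour spacing 2.25 nm, carved as the 404 sites closest to the
lattice origin (ties broken lexicographically). Chains are assigned to
nearest-neighbour site pairs in two phases: a Prim-style spanning phase
ordered by pair-midpoint distance from the centre guarantees a single
connected component with every crosslinker wired in, then remaining pairs
fill in by midpoint order (the reference carve offers 693 distinct pairs
for 692 chains; if a build requests more chains than distinct pairs,
pairs are doubled with a lateral offset). Chain beads are laid on helical
arcs whose chords equal the bond rest length, with the arc phase searched
against already-placed beads and residual few-hundredths-nm clashes
resolved by an iterative symmetric push-apart, so the built configuration
contains no overlaps at all — bonded or not — and no bond starts far from
its rest length. (Straight-line placement, the obvious alternative,
compresses bonds to 0.45 nm; under the unqualified rejection rule about a
tenth of those become geometrically deadlocked.)

This generator is a stand-in for the original (unpublished) generation
algorithm of the reference nanogel, calibrated through its lattice
spacing so that the relaxed gel reproduces the reported size. It produces
a slightly sharper-edged, more ordered gel than the original: see
Limitations.

## Equilibration and the pre-release state

`equilibrate` runs flexible dynamics and stops when consecutive
25 000-step window averages of the radius of gyration agree within 1%.
For the reference gel this halts at the model's equilibrium
(2Rng ≈ 20.8–21.1 nm, φ ≈ 0.086–0.090, stable for ≥240 000 further
steps across seeds); the equilibrated configuration defines the
pre-release gel for both modes — flexible runs continue its dynamics,
rigid runs freeze it, so both share one structure and volume fraction.
Rigid-mode input returns unchanged (nothing to relax). The structure
report records Rg; Rng = √(5/3)·Rg (the uniform-sphere equivalence —
exact for a homogeneously filled ball, and the standard way to convert a
gyration radius into a geometric one); φ as the summed volume of network
beads whose centres lie within Rng over (4/3)πRng³ (centre-counting
convention); the mean nearest-neighbour crosslinker distance; the
fraction of network beads beyond Rng; and Rcore, the radius where the
3-bin-smoothed radial density first falls below half its core average
(core = r < Rng/2; the search starts at Rng/2 so core layering
oscillations cannot trigger it). Rcore may also be set explicitly, which
the core-loading experiments use (9.1 nm for the reference gel).

## Release experiments

Loading places solute centres uniformly in the sphere of radius R_max
about the network centre of mass by rejection sampling against all beads
(R_max = Rng for throughout-loading, Rcore for core-loading; default
budget 10⁶ attempts per solute, exhaustion raising a jammed-loading
error). Release propagates the loaded system and applies first-exit
counting at each sample time: a solute whose distance from the
*instantaneous* network centre of mass exceeds the *fixed* pre-release
Rng is marked released permanently (an instantaneous-fraction variant
exists behind a flag for sensitivity checks). Released solutes continue
to diffuse and interact. Sampling is logarithmic, 64 points per decade
from 1 ps. The replicate structure mirrors standard practice: R release
repeats averaged into one curve; S independent averaged curves fitted;
parameters reported as mean ± SD over the S fits (defaults R = 18,
S = 3; the test suite and acceptance script use R = 3 at 20 ns, which
resolves every qualitative contrast they assert).

## Kinetics fitting

All fits are nonlinear least squares in linear f-space with uniform
weights (log–log regression would re-weight the early-time points and
shift n). The Ritger–Peppas window is every sample up to the first with
f ≥ 0.6. R² is reported on the fitted window and on the whole curve. The
delayed power law fixes t_d at the last sampled time with f = 0 — it is
not an adjustable parameter — and fits k, n on t ≥ t_d. The Fickian
series is truncated adaptively (remainder bound < 10⁻¹⁰) with the
short-time expansion 6√(x/π) − 3x used for x = Dg·t/Rng² < 10⁻³. The
analytic power-law baseline (n = 0.4297, k/(Dg/Rng²)ⁿ = 2.228,
scale-free in Dg and Rng) is computed on a uniformly spaced grid over the
60% window; a logarithmically spaced grid with uniform weights would
over-weight the √t regime and bias n to 0.45.

## What the simulated data do and do not show

The generator and engine emulate: excluded-volume-controlled transport in
a swollen neutral nanogel, the surface-void enrichment of loaded drug
(≈39% of 1-nm drugs within 1 nm of the border), the resulting
front-loaded release with n well below 0.43 for throughout-loading, the
delayed (t_d > 0), gradual, flexible-faster release of core-loaded drug
with n above 0.43, and the k–Dg relation. They do not include
electrostatic or hydrophobic drug–polymer attraction, hydrodynamic
interactions, solvent-quality effects, dialysis-membrane barriers, or
chemical specificity, so absolute time scales are ns-scale and far shorter
than experimental release curves.

## Known limitations

* The diamond-carve generator yields a sharper gel boundary and more local
  order than a gel generated by simulated self-assembly: ~7% of network
  beads lie beyond Rng (reported: ~10%), and the equilibrium
  nearest-neighbour crosslinker spacing is ~1.7 nm. Note a 3-D
  nearest-neighbour mean of 2.2 nm is geometrically incompatible with the
  reference gel's own density (a diamond arrangement at φ = 0.081 and
  Rng = 10.65 nm has edge ≈ 2.0 nm, and thermal min-of-neighbours
  statistics pull the nn mean below the edge length); distances measured
  in a 2-D cross-section, by contrast, exceed 3-D ones.
* The bead-spring model's equilibrium is slightly denser (φ ≈ 0.09) than
  the generated structure it models (φ ≈ 0.08); the reported structures
  are the model's equilibrium, not a hand-picked transient.
* For this equilibrium gel, rigid and flexible release curves at 1.75 nm
  nearly coincide, with flexible marginally ahead at early times; the
  rigid-ahead-early ordering seen for more lattice-like gels (we observe
  it for the pre-equilibrium structure) is not reproduced at equilibrium.
* Monodisperse chains only; no charge, pH response or swelling dynamics.
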