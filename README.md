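# nanorelease

Coarse-grained Brownian-dynamics simulation of diffusion-controlled drug
release from nanogels, with the full release-kinetics analysis toolkit.

Nanogels — crosslinked polymer networks of nanometric size — are widely
studied drug carriers, and their release curves are routinely analysed
with closed-form models whose assumptions (perfect sink, uniform loading,
homogeneous matrix) real nanogels violate. `nanorelease` simulates the
release process explicitly: monomers, crosslinkers and drug molecules are
hard spheres in implicit solvent, the network is a bead-spring gel, and
every particle performs overdamped Brownian motion with hard-sphere
rejection, so steric (excluded-volume) polymer–drug interaction is the
only transport obstacle. Both **rigid** gels (frozen network) and
**flexible** gels (Hookean bonds, mobile network) are supported, with drug
loaded either throughout the gel or confined to its dense core. The
package is aimed at polymer/soft-matter researchers who want desk-scale,
fully reproducible in-silico release experiments and a careful look at
what fitted kinetic parameters do and do not mean.

## Model

* Beads: monomers and crosslinkers of diameter 0.65 nm, drugs of diameter
  0.75–1.75 nm; free diffusion coefficients from Einstein–Stokes,
  D₀ = kBT/6πηR (water at 293 K by default).
* Solute move (Cichocki–Hinsen): each Cartesian component of a trial step
  is √(2·D₀·Δt)·N(0,1); the step is rejected if any two particles would
  overlap. Δt = 3 ps.
* Network beads (flexible mode) add the overdamped drift D₀·F·Δt/kBT with
  Hookean bond forces F = −kₑ(r−r₀)r̂, kₑ = 0.4 N/m, r₀ = 0.65 nm.
* Release: a drug molecule counts as released the first time its distance
  from the network centre of mass exceeds the gel radius Rng (no perfect
  sink; released molecules keep diffusing).

Analysis (in `nanorelease.kinetics`):

* Fickian sphere solution
  f(t) = 1 − (6/π²) Σ n⁻² exp(−Dg·n²π²t/Rng²),
* Amsden-type obstruction estimates of Dg for rigid and flexible networks,
* Ritger–Peppas power law f = k·tⁿ over the first 60% of release
  (n = 0.43 is the classical diffusive value for spheres, with
  k ≅ 2.246·(Dg/Rng²)ⁿ),
* the delayed power law f = k·(t−t_d)ⁿ for core-loaded gels, and a
  two-parameter Weibull comparison fit f = 1 − exp(−a·t^b).

The reference nanogel is built from 692 tetramer chains joined by 404
crosslinkers (diamond-lattice carve, then relaxed by flexible Brownian
dynamics) and holds 100 drug molecules.

## Worked example

```python
from nanorelease import (build_topology, equilibrate, structure_report,
                         SimulationParams, LoadingSpec, RNGStream,
                         run_replicates, fit_power_law, dg_obstruction,
                         dg_from_fit, stokes_einstein)

topo, lattice = build_topology(n_chains=692, chain_length=4, n_crosslinkers=404)
gel = equilibrate(lattice, topo, SimulationParams(mode="flexible", seed=7))
rep = structure_report(gel, topo)
print(f"2Rng = {2*rep.Rng:.1f} nm, phi = {rep.phi:.3f}, "
      f"{100*rep.frac_beyond_Rng:.0f}% of beads beyond Rng")

spec = LoadingSpec(n_drug=100, solute_diameter=1.0, R_max=rep.Rng)
params = SimulationParams(mode="rigid", seed=7, n_steps=6667)   # 20 ns
curve = run_replicates(gel, topo, params, spec, rep.Rng,
                       n_replicates=3, base_rng=RNGStream(7))
fit = fit_power_law(curve, f_cut=0.6)
print(f"f(20 ns) = {curve.f[-1]:.2f}; Ritger-Peppas n = {fit.n:.2f}, "
      f"k = {fit.k:.2f} ns^-n (R^2 = {fit.R2:.3f})")

dg_fit = dg_from_fit(fit.k, fit.n, rep.Rng)
dg_theory = dg_obstruction(stokes_einstein(0.5), rep.phi, Rs=0.5, Rp=0.325,
                           mode="rigid")
print(f"Dg from k: {dg_fit:.2f} nm^2/ns (obstruction theory: {dg_theory:.2f})")
```

prints

```
2Rng = 20.9 nm, phi = 0.089, 7% of beads beyond Rng
f(20 ns) = 0.70; Ritger-Peppas n = 0.34, k = 0.29 ns^-n (R^2 = 0.985)
Dg from k: 0.29 nm^2/ns (obstruction theory: 0.27)
```

Reading the output: the equilibrated gel is ~21 nm across at 9% polymer
volume fraction; 70% of a 1-nm drug escapes within 20 ns. The fitted
exponent n = 0.34 sits well below the classical 0.43 — release from a
nanogel is front-loaded because drug housed in surface voids leaves almost
immediately (surface anisotropic diffusion) — so n alone would misleadingly
suggest "non-diffusive" transport. The prefactor k is the robust quantity:
inverting k ≅ 2.246(Dg/Rng²)ⁿ recovers the in-gel diffusion coefficient
within ~10% of the obstruction-model estimate.

A `nanorelease` console script exposes the same pipeline
(`nanorelease build`, `nanorelease release run --config exp.yaml`,
`nanorelease kinetics fit curve.csv`, `nanorelease experiment run ...`);
YAML experiment configs and CSV/XYZ outputs carry the config hash and all
seeds, so every curve is bit-reproducible.

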