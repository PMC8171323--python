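# photoseam

Automated exploration of conical-intersection seams and photochemical
product networks on multi-state model potential surfaces.

## The problem

When a molecule absorbs a photon it evolves on an excited electronic
state until it reaches the *intersection seam* — the set of geometries
where two adiabatic states are degenerate — and funnels back down through
a conical intersection (CI) toward ground-state products.  Which products
form, and in what proportion, depends on *where* on the seam the molecule
crosses and on the local CI topography.  Mapping seams, their
minimum-energy conical intersections (MECIs), and the products reachable
from each is therefore the central task of automated photochemical
reaction discovery, but doing it by hand requires expert guesses at every
step.

`photoseam` implements a six-stage discovery-and-refinement pipeline that
needs no prior knowledge of the system:

1. **Seam metadynamics** — thermostatted dynamics on the mean energy
   E̅ = (E_i + E_j)/2 of a state pair, restrained to the seam by a gap
   penalty that is harmonic for ΔE < δ and linear above (C¹ at the
   switch), with repulsive Gaussian bias deposited in an aligned-RMSD
   collective variable to force exploration of new seam basins.
2. **Seam sampling** — harvest of all frames with ΔE below a threshold
   (default 0.1 energy units).
3. **CI selection** — permutation-aware alignment, K-means clustering
   with an elbow (maximum-curvature) choice of k, Lagrange–Newton MECI
   refinement of cluster exemplars, and deduplication.  Each MECI is
   characterized by its orthonormal branching-plane vectors **g** (energy
   difference gradient) and **h** (scaled derivative coupling) and by the
   slopeness
   σ = ‖P₍g,h₎ ∇E̅(R_CI)‖ — zero for a peaked cone, large for a sloped one.
4. **Cone sampling** — random displacements on the branching plane,
   r = r₀ + l cos(α) g + l sin(α) h with l = cR, α = 2πb and b, c uniform
   on (0, 1), optionally windowed on the energy gap by rejection.
5. **Photoproduct search** — gradient-following minimization of every
   cone point on the lower state, then a census of which stationary point
   each reaches.
6. **Refinement** — growing-string minimum-energy paths with a climbing
   image: ground-state paths between products (barrier tables with
   intermediate detection) and seam-constrained paths between MECIs, with
   optional re-profiling of σ and the product census along the path.

For higher excitations the pipeline runs as a cascade: cone points of the
S_n/S_{n−1} seam seed new seam dynamics on S_{n−1}/S_{n−2}, down to S₁/S₀.

Electronic structure is abstracted behind a `SurfaceModel` interface.
Five analytic diabatic model families ship with the package (a 2-D
Jahn-Teller cone, its 3-D curved-seam extension, a Müller–Brown-based
two-state photochemical landscape, a three-state cascade test bed, and a
Morse particle cluster), all with exact gradients and nonadiabatic
couplings, so the entire pipeline runs in seconds on a laptop.  Any
backend with the same `evaluate` signature — including an external
quantum-chemistry engine — can be plugged in.

## Worked example

```python
from photoseam import make_model
from photoseam.selection import optimize_meci, slopeness
from photoseam.cone import sample_cone
from photoseam.products import census

model = make_model("two_state_photo")          # Muller-Brown-based landscape
meci = optimize_meci(model, (0, 1), model.geometry([0.83, -0.14]))
print(meci.geometry.coords, meci.e_mean, meci.sigma)
samples = sample_cone(model, meci, R=0.075, n=500, gap_window=(0.0, 0.5),
                      seed=7)
cens, products = census(model, samples)
print(cens.fractions)
```

prints

```
[ 0.83034023 -0.13729367] -0.5080011352745372 1.9380593133046443
{'product_1': 0.5, 'product_0': 0.5}
```

The optimizer has landed on the lowest seam minimum of the landscape
(mean energy −0.508 model units) and found it strongly sloped
(σ ≈ 1.94).  The 500 branching-plane points split evenly between the two
ground-state basins flanking the seam: this MECI is a 50/50 branching
funnel.

The full pipeline is driven by a YAML config, either from Python
(`photoseam.workflow.run_workflow`) or the CLI, whose subcommands mirror
the stages:

```bash
photoseam run-all -c config.yaml -o out --seed 11
photoseam seam-md -c config.yaml -o out          # or stage by stage
photoseam select-cis -c config.yaml -o out --frames out/harvested.dat
```

Reports are schema-versioned JSON and byte-identical for identical seeds;
interrupted runs resume from per-stage checkpoints.

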