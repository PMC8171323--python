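# Methods

This note records the models, algorithms and numerical choices behind
`photoseam`, in the order the pipeline uses them, together with the
reasoning for design decisions that were genuinely open.

## Model surfaces

Every packaged surface is an analytic symmetric diabatic matrix H(x).
Adiabatic states come from `numpy.linalg.eigh`; gradients from
Hellmann–Feynman, dE_i = v_iᵀ(dH)v_i; derivative couplings from
d_ij = v_iᵀ(dH)v_j / (E_j − E_i).  Eigenvector phases are fixed by making
the largest-magnitude component positive, which keeps gradients and
couplings from flipping sign between neighboring evaluations (the
coupling is still a gauge-dependent quantity; only its magnitude and the
plane it spans are physical).  Pairs with gap < 10⁻¹² are flagged
degenerate and their 1/ΔE coupling left undefined; downstream code uses
the finite numerator v_iᵀ(dH)v_j instead.

Units are model units throughout with k_B = 1; every threshold in a
configuration is interpreted in the active model's units.  The documented
molecular-scale defaults (0.1 eV harvest, R = 0.075, 300 K) informed the
model-unit defaults but do not transfer literally — model wells are of
order one energy unit, so the default temperature is 0.05.

Family design:

* `jt_cone` — H₁₁/₂₂ = (ω/2)r² ± κx + sx, H₁₂ = λy.  The textbook linear
  vibronic cone: a single CI at the origin, peaked for s = 0, slopeness
  exactly |s| otherwise.  κ = 0 or λ = 0 is rejected (degeneracy along a
  whole axis).
* `jt_cone_3d` — adds a z coordinate with diagonal terms (ω/2)z² ± az.
  The degeneracy condition (κx + az = 0, y = 0) becomes a line, and the
  mean energy along it is an analytic parabola with a unique minimum at
  z* = s(a/κ)/(ω(1 + (a/κ)²)) — a closed-form MECI oracle.
* `two_state_photo` — lower diabat: the Müller–Brown sum of four
  anisotropic Gaussians scaled by 0.01; upper diabat: the same surface
  displaced by (0.45, −0.3) and raised 0.35; constant coupling
  γ = 10⁻⁶.  The displacement/offset were chosen once so that the
  diabatic crossing curve passes between the wells and carries several
  seam minima (the three lowest at mean energies ≈ −0.508, −0.496 and
  −0.336), while the lower adiabatic state keeps ≥ 3 product minima.  A
  constant coupling means the branching space is one-dimensional and the
  true minimum gap is 2γ = 2·10⁻⁶ — far below every tolerance, so the
  crossing behaves as a genuine seam for the pipeline.
* `three_state_cascade` — ground diabat b(x² − 1)² + (ω/2)y² (two product
  wells at x = ±1 plus, adiabatically, the excited diabat's minimum
  poking through inside the crossing ring), two displaced excited
  paraboloids, couplings proportional to y.  Parameters were chosen once
  so that both the S2/S1 crossing (E ≈ 0.98) and the S0/S1 crossings
  (E ≈ 0.93–0.97) lie below the S2 energy at the Franck–Condon point
  (1.384), which is what the cascade protocol requires.  Because the
  couplings vanish only at y = 0, the exact degeneracies are isolated
  points rather than curves; seam dynamics still samples the low-gap
  crossing ribbons around them.
* `particle_cluster` — N identical particles, pairwise Morse lower
  state, stretched-pair upper state, constant coupling.  Exists to
  exercise permutation-aware alignment and the XYZ path.

## Alignment

Superposition uses the Kabsch construction (SVD with determinant forced
to +1, equivalent to the quaternion method) for 3-D, the planar analogue
for 2-D, and — deliberately — **no** alignment for single-particle
abstract geometries, where the collective variable is the plain
Euclidean distance.  Reflections are never admitted, so enantiomeric
products stay distinct.  RMSD is mass-unweighted.

Permutations over identical labels are searched exhaustively for groups
of ≤ 6 interchangeable particles (benzene-like cases stay exact) and by
an iterated Hungarian assignment above that, warm-started from a
rotation-invariant feature (each particle's sorted distance vector to
all others) so large pure relabelings are undone reliably.

The RMSD gradient uses the envelope theorem: at the optimal rotation,
translation and (locally stable) permutation, only the explicit
dependence on the mobile coordinates survives.  At RMSD = 0 the gradient
is defined as zero.

## Seam metadynamics

The propagated potential is the pair mean energy plus the gap restraint
(configurable to the upper state instead); the restraint is harmonic
below δ and linear above, C¹-continuous, with defaults δ = 0.1 and
k = 100 in model units.  k was set so that at the default temperature
the walker's equilibrium gap distribution sits well inside 2δ: the
linear-branch restoring force kδ must dominate k_BT at the scale of δ.
Integration is velocity Verlet started from zero velocity; the
thermostat is stochastic velocity rescaling (single global factor,
τ = 0.5); the cold-start step draws Maxwell velocities at the
partial-coupling temperature rather than rescaling a zero vector.  A
"conserved" quantity (kinetic + potential − accumulated thermostat work)
is logged per frame; with the restraint off its drift is the integrator
stability diagnostic.

Bias hills (default height 0.025 = 0.5 k_BT, width 0.1 in RMSD space,
one hill per 50 steps, plain non-tempered scheme) are stored aligned to
the start frame so the bias is rigid-motion invariant.  On a
point-like seam such as the symmetric cone's, a growing bias necessarily
fights the restraint — there is nowhere along the seam to escape to — so
the seam-residence property (≥ 80 % of post-warm-up frames within 2δ) is
a statement about the restraint and is measured with bias off; the
bias's job, escaping between seam basins, is measured on the
two-dimensional landscape where basins exist.

## MECI optimization

The constrained search minimizes the pair mean energy subject to
gap = 0: a Lagrange–Newton scheme with a least-squares multiplier
estimate, damped-BFGS Hessian of the Lagrangian, and a KKT step under a
trust radius halved whenever the merit function E̅ + μ·gap worsens.  Two
safeguards matter in practice:

* Near a constant-coupling seam the constraint gradient ∇gap → 0 while
  the gap floors at 2γ.  The step then switches to minimizing the mean
  energy projected orthogonal to the *gap-lifting* directions — both g
  and h for a genuine conical point, g alone when the h-vector is
  degenerate (flagged fallback).  Convergence likewise requires the
  seam-tangent-projected gradient below tol_grad; projecting out the
  full (g, h) pair would make any on-seam point of a 2-D model look
  stationary.
* If the trust region collapses, an exterior quadratic gap penalty with
  weight escalation (×10 per cycle, 6 cycles) restarts the search.

Defaults: tol_gap = 10⁻⁵, tol_grad = 10⁻⁴, 200 iterations.  On the cone
models the KKT step solves the (exactly linear) radial constraint in one
shot, so converged geometries are accurate to ~10⁻⁸.

Branching-plane construction uses g = ∇(E_j − E_i) and the finite
Hellmann–Feynman numerator h = v_iᵀ(dH)v_j, rotated within their plane
to orthogonality (the rotation simultaneously absorbs the arbitrary
mixing of near-degenerate eigenvectors) and normalized.  When h is
numerically parallel to g — the one-dimensional branching space of a
constant-coupling model — the plane is completed with a deterministic
unit vector orthogonal to g so that cone sampling still covers a disk.
Slopeness is the norm of the branching-plane projection of the
mean-energy gradient at the converged geometry.

Clustering operates on aligned coordinate vectors (K-means needs a
vector space, and a distance matrix would not give centroids); k is
chosen as the maximum of the second difference of the inertia-vs-k curve
(ties toward smaller k), and centroids are snapped to the nearest actual
frame because an average of aligned seam frames need not be anywhere
near the seam.

## Cone sampling and the product census

The displacement law r = r₀ + cR·(cos 2πb · g + sin 2πb · h) is applied
literally; the gap window is enforced by rejection (draw budget 100n)
rather than by retuning R, which preserves the radius-uniform law
exactly.  Two named default sets are kept: the wide-open lower-seam
window (0.0–0.5, n = 500, R = 0.075) and the cascade re-seeding window
(0.1–0.5, n = 10).  The model-unit radius must be set per surface; for
the cascade test bed R = 0.4 reaches the 0.1 gap floor that the
molecular-scale R = 0.075 cannot.

Product optimizations are plain gradient-following (BFGS with
backtracking and a 0.2-length-unit step cap to limit ridge hopping); no
momentum, no thermal noise.  Products are deduplicated by
permutation-aware RMSD (< 0.05) plus energy (< 0.01) and labeled by
ascending energy.  Censuses taken around different MECIs share one
product registry and are re-tallied once the registry is final, so
labels are comparable across MECIs and along paths.

## Paths

Both path objectives run on the same double-ended growing string with a
climbing image and improved (upwind) tangents; interior nodes are
re-spaced to equal arc length each macro-iteration, and per-node step
lengths adapt by sign damping (halved on force reversal), which keeps the
relaxation stable regardless of how stiff the seam penalty is.  The
climbing node is exempt from re-spacing and converges to a true
stationary point; when the path maximum is a *cusp* (a ground-state
ridge where two surfaces cross, smoothed only at the 2γ scale), the
gradient criterion is unattainable and convergence is instead declared
when the climbing node's adaptive displacement collapses below 10⁻⁸ —
the position, and hence the barrier, is resolved even though the
gradient is not small.

Seam paths add two elements beyond the penalty of the original design:
images are snapped back onto the seam by pure gap-Newton steps (which
cannot slide along the seam) every macro-iteration, and the initial
chain is generated by a predictor–corrector walk *along* the seam from
one endpoint to the other, choosing the lower-passing arc when the seam
loops.  This matters because a chord-initialized string on a strongly
curved seam relaxes onto the wrong branch.  On a one-dimensional seam
the path is the seam arc itself: interior nodes have no transverse
freedom and are carried by re-spacing alone, while the climbing node
ascends along the seam tangent.  The penalty-weight escalation (×10, up
to 5 times, until all image gaps < gap_tol = 10⁻³) remains as a backstop
for seams the tracer cannot handle — including pointlike degeneracies,
where an all-degenerate connecting path does not exist and the result is
honestly reported unconverged.

Barrier tables path all ordered product pairs; a cell reports a third
product's label instead of a number when an interior image falls within
the product-dedup tolerance of it.  A path whose maximum sits at an
endpoint (within 10⁻⁶) is labeled barrierless.  Path profiling
re-converges each image to the seam, recomputes σ and the census, and
attaches percentile bootstrap intervals (1000 seeded replicates over the
cone points) to the product fractions.

## Workflow and determinism

A single global seed spawns per-stage seeds through
`numpy.random.SeedSequence` keyed on stage indices, so any stage can be
rerun in isolation and full reports are byte-identical across runs of
the same configuration.  For that reason wall-clock timing goes to the
plain-text log only, never into the report JSON.  Stage outputs are
checkpointed as JSON; a resumed run replays cached stages (including
their log lines) and produces a report equal to an uninterrupted one.

Default problem sizes were chosen to characterize the packaged models
well at desk scale: 4000 metadynamics steps per seam level (cascade
levels shorter, since there is one trajectory per upper-level cone
seed), k_max = 6 clusters, 500 lower-seam cone points, 10 cascade seeds
per upper MECI, 21 ground-path and 11 seam-path images.

## What the models do and do not show

The analytic surfaces reproduce the *structure* of the problem — seams
with several minima, peaked and sloped intersections, branching-plane
product selectivity, cascade connectivity — with exact derivatives, so
passing tests validate the pipeline's algorithms and bookkeeping, not
any molecular prediction.  They omit: high dimensionality (seam
codimension-2 geometry in many coordinates), electronic-structure noise
and state-ordering swaps, permutational symmetry in the reactive system
itself (the Morse cluster exercises alignment only), and any velocity or
nonadiabatic-dynamics effects on product ratios — the census is a
zero-velocity, gradient-following map by construction.

## Known limitations

* The seam tracer assumes a one-dimensional seam tangent space; for
  higher-dimensional seams the string falls back to chord growth plus
  penalty/snapping, which is slower and may find a non-minimal arc.
* The Hungarian permutation heuristic is not guaranteed optimal above
  the exhaustive limit (6 interchangeable particles).
* The cascade test bed's exact degeneracies are isolated points, so its
  "seam paths" between lower-level MECIs are reported unconverged — a
  property of the model, preserved deliberately as an honest negative.
* No well-tempered metadynamics, free-energy reconstruction, multiple
  walkers, or second-order seam sampling with velocity assignment.
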