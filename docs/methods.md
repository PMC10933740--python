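# Methods

`pgk` implements the structural-inference chain for disordered, low-density,
diamond-like packings of dielectric spheres — the morphology behind the
angle-independent structural colour of photonic glasses such as the chitin
sphere assemblies in longhorn-beetle wing scales.  The chain has four legs:
a generative patchy-particle sedimentation model, real-space contact and
bond-orientational-order (BOO) analysis, reciprocal-space SAXS forward
models and fits, and a tomogram emulator + sphere extractor that stands in
for FIB-SEM data.  This note documents the models, the defaults and why
they are what they are, the numerical choices, and the limits of what the
synthetic tests demonstrate.

## 1. Patchy-particle sedimentation model

### Interactions

Particles are rigid spheres of contact diameter σ (default 210 nm, the
SAXS-derived diameter of the blue-scale spheres) carrying four attractive
patches whose body-frame axes point at exact tetrahedral angles
(cos θ = −1/3).  All energies are in k_BT and all pair terms use the steep
2n–n Lennard-Jones form with n = 24,

    U_LJ(r; ε, s) = 4ε[(s/r)^{2n} − (s/r)^n],

whose minimum sits at r = 2^{1/n}s ≈ 1.03 s.  The pair energy of particles
i, j at centre distance r is

    U_ij = U_WCA(r; ε_wca, σ)  +  f_i f_j · U_LJ(r; ε_patch, σ)
           + U_LJ(r; ε_body, σ_b),

* **WCA core** (ε_wca = 10): the truncated-shifted repulsive branch, exactly
  zero beyond 2^{1/n}σ — the excluded volume of the chitin sphere.
* **Patch attraction** (ε_patch = 8): a centre–centre radial LJ modulated by
  the mutual alignment factor f_i f_j (below).  A perfectly bonded pair
  sits at 1.03 σ with energy −8 k_BT.
* **Body–body LJ** (ε_body = 3) evaluated at its own length scale
  σ_b = `body_sigma_factor`·σ.  The default factor 0.5 places this term at
  the sphere *radius*, where it contributes ~10⁻⁶ k_BT at contact: apart
  from the patches, contacts are effectively purely repulsive.  Setting
  `body_sigma_factor = 1` moves its minimum to the contact distance,
  turning the particles into uniformly sticky spheres.

The factor-0.5 default is a substantive modelling decision, made after
measuring both variants.  A 3 k_BT attraction of ~0.05 σ range at every
contact corresponds to a Baxter stickiness τ ≈ 0.08, inside the
condensation region: sediments of such spheres collapse into a dense
sticky liquid with 7.5–8 touching neighbours (mode 8) at every gravity,
patch width and run length we tried, and no tetrahedrally coordinated
state exists.  With non-patch contacts repulsive, the sediment instead
forms the open tetrahedral network this model exists to produce
(mode n_touch = 4).  Only the repulsive-otherwise reading is consistent
with a four-coordinated disordered packing at φ ≈ 0.46.

### Patch alignment factor

For a pair along unit vector u, each particle contributes
f = g(θ), where θ is the angle between u (or −u) and that particle's
best-aligned patch axis, and

    g(θ) = exp(−θ² / 2δ²) · w(θ),

with δ = 30° (`patch_halfwidth`) and w a C¹ cosine-squared switch equal to
1 below 2δ and identically 0 above 3δ.  The product f_i f_j is 1 for
exactly facing patches, symmetric under particle exchange, and exactly 0
once either patch is ≥ 90° off axis, so non-facing contacts feel no
attraction at all.  The hard outer cutoff (rather than a bare Gaussian)
keeps the "repulsive otherwise" property strict; the Gaussian interior
keeps torques smooth.  Forces and torques are the exact analytic gradients
of this energy; the test suite verifies them against central differences
to 10⁻⁶ relative, including the best-patch selection (smooth everywhere
except the measure-zero patch-switching set).

### Dynamics and protocol

Rigid-body Langevin dynamics: BAOAB splitting for translation and the
quaternion analogue for rotation (space-frame angular velocities, unit
moment of inertia 2/5·m·(σ/2)² with m = 1).  Reduced units σ = k_BT = m = 1;
defaults dt = 0.002, translational friction 1, rotational friction 0.3.
At zero friction the scheme reduces to velocity Verlet; `run_langevin`
runs a 100-step zero-friction probe before production and refuses time
steps that drift more than 1% — dt = 0.002 drifts ~10⁻⁴ over 10⁴ steps at
the stiff n = 24 potential.  Pair interactions are truncated and shifted
at r_cut = 1.5 σ (the n = 24 tail is ~10⁻³ k_BT there); candidate pairs
come from a cell list with a 0.32 σ skin rebuilt every 25 steps (results are independent of these list parameters
to floating-point noise; the skin comfortably covers per-chunk drift at
k_BT = 1).

The sedimentation geometry is a laterally periodic box (default 8 σ × 8 σ)
with a WCA bottom wall at z = 0 and an open top.  `make_settling_start`
places N particles (default 1080) on a dilute jittered grid with random
orientations; a constant gravity g (k_BT/σ per particle) settles them into
a bed over ~100 000 steps (200 reduced time units).  The bed density is
measured in the *bulk*: a z-slab excluding 1.5 mean diameters above the
wall and below the free surface (98th height percentile), with the exact
spherical-cap-corrected packing fraction.

`equilibrate_to_density` adjusts g by bisection on log g (bed density
increases monotonically with gravity in the disordered regime) until the
bulk packing fraction is within ±0.02 of the target.  The shipped default
g = 0.65 was calibrated once against the φ = 0.46 target at N = 1080 and is
used as the bisection starting point, so a typical run needs a single
settling simulation.  The calibration scan also reproduces the two
regimes reported for this model: moderate gravity gives the disordered
tetrahedral bed (n_touch mode 4), strong gravity (g ≳ 2) compacts and
begins to order the bed (mode 8–9, climbing q̄6) — the ordered
high-gravity branch.

### What the sediment reproduces

At φ ≈ 0.46 the bulk mean touching-neighbour count (15 nm gap, see §3) is
4.5 ± 0.5 across seeds with the distribution mode at 4 — the tetrahedral
network plus occasional incidental contacts.  This is the model's central
prediction: a mechanically settled sphere assembly far below random-close-
packing density, held at four-fold coordination by directional adhesion.

## 2. Reference structures and jammed packings

`build_lattice` produces ideal periodic crystals (sc, fcc, bcc, hcp on an
orthorhombic 4-site cell, diamond-cubic with its 8-site conventional
cell), in "touching" mode with the sphere radius set to half the
nearest-neighbour distance.  Bases are shifted off the cell faces by a
fixed fractional offset — a pure translation, irrelevant under periodic
boundaries but convenient for voxelisation fixtures.

`generate_jammed_packing` is a soft-sphere growth-and-quench protocol:
monodisperse (optionally Gaussian-polydisperse) particles in a periodic
unit box are inflated in packing-fraction steps of 0.01, minimising the
harmonic overlap energy V = Σ ½(1 − d/σ_ij)² after each step with FIRE;
jamming is declared when the quench can no longer reach the energy floor
(10⁻¹⁶ per particle), the onset is bisected to 2.5·10⁻⁴ in φ, and
contacts are measured after one further quench at a fixed 2.5·10⁻⁴
overcompression so every force-bearing contact has a resolvable overlap.
Rattlers (< 4 contacts, pruned iteratively) are flagged in the labels and
excluded from the contact statistics but included in φ.  At N = 1000 this
lands at φ = 0.636 ± 0.003 and 6.1 ± 0.05 non-rattler contacts — the
maximally-random-jammed benchmark (φ ≈ 0.64, isostatic Z ≈ 6).  The
protocol is a fast quench; slower annealing schedules would jam slightly
denser, and the residual ~0.13 above-isostatic contacts reflect the
measurement overcompression.

## 3. Contact statistics

Particles i, j touch when the minimum-image centre distance satisfies
d_ij ≤ r_i + r_j + gap, with gap = 15 nm by default — one voxel of the
emulated tomograms, the same criterion used on the real data.  The
contact graph is built with a k-d tree over periodic ghost images (O(N)
expected) and is tested for exact agreement with the all-pairs brute
force.  Reported statistics: integer histogram, mean ± sd, and mode.  A
histogram of integers cannot peak at 4.5; the "4.5 ± 2" headline statistic
of such data is the mean ± sd, and both mean and mode are always emitted.

Packing fractions are computed analytically (sphere volumes with exact
spherical-cap corrections at region faces; spheres cut by region edges or
overlapping spheres trigger a Monte-Carlo fallback) or by seeded
Monte-Carlo point sampling with a binomial standard error; the two agree
within 3 standard errors on every tested fixture.

## 4. Bond-orientational order

Steinhardt invariants: q_lm(i) is the mean of the orthonormal spherical
harmonics (Condon–Shortley phase) over i's bond directions,
q_l = √(4π/(2l+1) Σ_m |q_lm|²) ∈ [0, 1].  The neighbourhood is the same
15 nm-gap distance criterion as the contact count.  Both the plain q_l and
the Lechner–Dellago averaged q̄_l (q_lm averaged over {i} ∪ neighbours
before the invariant) are computed per particle; ensemble values are means
of per-particle invariants over particles with ≥ 1 neighbour.

Classification is nearest-reference Euclidean distance in the (q4, q6)
plane against five references: HCP, BCC, FCC, diamond (regenerated
deterministically from `build_lattice`; for perfect lattices plain and
averaged invariants coincide) and an MRJ point computed from this
package's own jammed packings (provenance "computed"; N = 256, fixed
seed).  The BCC reference uses the conventional 14-neighbour shell
(q4, q6 = 0.036, 0.511), the literature fingerprint, while contact
*counting* on BCC keeps the strict touching criterion (8).  Note that the
diamond fingerprint (0.509, 0.629) equals the 8-neighbour cube-vertex
value: two inverted tetrahedra merge for even l, which is why four-bond
environments need no separate convention.

For *disordered* tetrahedral networks the Lechner–Dellago average is
diluted by the uncorrelated bond-rotation angles between neighbouring
tetrahedra, pulling q̄ toward the origin; the plain per-particle
invariants retain the local tetrahedral signature.  Classification of
disordered assemblies therefore uses the statistic that discriminates in
practice (see `classify_structure` callers); both are always reported.

## 5. SAXS models

Forward model: I(q) = scale·⟨P(q;R)⟩·S(q) + background with the exact
sphere form factor (Guinier at low q by construction), a truncated
(R > 0) Gaussian diameter distribution integrated on a 35-point grid with
volume-squared weighting, and the structure factor in the
local-monodisperse approximation (S at the effective hard-sphere radius,
default the mean radius).  S(q) is either the analytic Ashcroft–Lekner
Percus–Yevick hard-sphere solution (series-guarded below qσ = 0.2;
S(0) = (1−φ)⁴/(1+2φ)²) or the Baxter sticky-hard-sphere PY solution with
stickiness τ (smaller root of the Baxter quadratic; no real root raises a
parameter-region error).  The two implementations are algebraically
independent and agree to 10⁻³ in the τ → ∞ limit, which the tests pin.

The Debye oracle computes I(q) directly from coordinates,
I(q) = Σ_ij F_i F_j sinc(q d_ij) with per-sphere amplitudes — O(N²) per q
point, capped at N = 2000 — and cross-checks the analytic model's
structure-factor peak on jammed packings.

Fits are weighted (1/σ²) Levenberg–Marquardt via lmfit with bounds,
optional fixed parameters, and the hard-sphere radius tied to d/2 by
default.  Synthetic round-trips at the study conditions (d ∈ {210, 254} nm,
10% polydispersity, φ ∈ {0.46, 0.53}, 2% noise on a 200-point log grid over
q = 0.004–0.2 nm⁻¹) recover d and φ within 5% and the diameter sd within
20%; fitting the sticky model to pure hard-sphere data drives τ > 50,
i.e. the stickiness parameter correctly collapses when unneeded.

## 6. Tomogram emulation and extraction

`voxelize` marks a voxel occupied iff its centre lies inside a sphere
(periodic wrap honoured) and stores the particle index as the label, ties
to the nearest surface; pitch defaults to 15 nm.  `degrade` emulates
acquisition damage in three seeded, deterministic stages:

1. **Shrinkage** — a global isotropic contraction by `shrink_factor`
   (order-0 zoom, labels preserved).  Electron-dose shrinkage contracts
   the whole Pt-filled sample, centres included; this is exactly the
   deformation the later ×1/shrink voxel-volume rescale correction
   undoes.  (Per-particle erosion with fixed centres was tried first and
   rejected: the global rescale correction then moves centres that never
   moved, destroying the contact statistics it is meant to restore.)
2. **Surface deformation** — a Gaussian random field (correlation length
   50 nm, amplitude in nm) added to the signed Euclidean distance map
   before re-thresholding: smooth particle-shape distortion.
3. **Voxel noise** — Bernoulli flips at `noise_rate`.

`extract_spheres` is the classical chain: Euclidean distance transform →
Gaussian smoothing (0.15 × expected radius) → local maxima with greedy
Euclidean suppression at 0.6 × expected diameter → marker-controlled
watershed → per-label centroid and equivalent-volume radius
(3V/4π)^{1/3}.  The marker constants were calibrated on synthetic
fixtures (touching lattices and dense disordered packings at 12–14 voxels
per particle diameter); with them, particle counts are recovered within
5% and centroids within ~5 nm (a third of a voxel) through the full
degradation chain.  `rescale_assembly` (positions, radii, box × factor)
and `regularize_spheres` (uniform target diameter, centres kept, overlap
report in metadata) implement the two corrections applied to real
shrunken tomograms.

## 7. Seeds and determinism

Every stochastic stage takes an explicit integer seed and is bit-
reproducible given it; the pipeline derives stage seeds from the single
`RunConfig.seed` via `numpy.random.SeedSequence`.  The acceptance script
spawns per-replicate seeds the same way and keeps them below 2³¹.

## 8. Problem sizes

Defaults were chosen so each stage is a desk-scale computation: sediments
N = 1080 (the study size) for 100 000 steps (~3 minutes each with the
compiled kernels), jammed packings N = 1000 (~30 s each), tomogram
fixtures of 200–400 particles at 15 nm pitch, SAXS grids of 200 points.
Property tests use smaller instances (N ≤ 500) of the same generators.

## 9. What passing tests do and do not show

The synthetic generators emulate the *statistical* structure of the real
data: sphere polydispersity, finite voxel size, shrinkage, smooth
deformation and salt-and-pepper noise.  They do not emulate FIB-SEM slice
registration errors, anisotropic milling artifacts, segmentation-model
(Weka) bias, detector point-spread or instrument smearing in SAXS, or the
membrane-assisted in-vivo growth process of the real scales.  Passing the
round-trip tests therefore shows the *analysis chain* is unbiased at the
stated noise levels, not that those noise levels capture every artifact
of the instruments.  Similarly, the patchy-particle model is an idealised
generative surrogate: its reproduction of the target contact statistics
supports the structural interpretation, not a claim about the biological
assembly mechanism.

## Known limitations

* The jamming protocol is a fast quench aimed at the MRJ point; it is not
  an event-driven Lubachevsky–Stillinger implementation and does not
  produce the strict-jamming φ = 0.60 family.
* The patch interaction is a modulated-centre (continuous Kern–Frenkel)
  form; site–site patch potentials with off-centre patch beads would give
  slightly different bond-bending stiffness.  Patch width (30°), friction
  and run lengths are engineering choices validated against the printed
  coordination outcomes, not measured quantities.
* `equilibrate_to_density` assumes density increases with gravity; in the
  strong-gravity ordered regime that assumption, and the disordered-bed
  interpretation, both break down — targets near or above φ ≈ 0.55 are
  outside the intended envelope.
* The Debye oracle treats the periodic minimum image as an isolated
  orientation-averaged system; its lowest-q decade on small boxes carries
  finite-size artifacts (tests window them out).
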