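# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mxindex`.

## Coordinate model

A rotation-method experiment is described by four components. The beam
carries a wavelength λ (Å) and a unit direction from source to crystal;
its wave vector is **s**₀ with ‖**s**₀‖ = 1/λ. The detector is a single
flat panel: unit fast/slow axes **d**_x, **d**_y in the lab frame, an
origin vector **d**₀ (mm) to the outer corner of pixel (0, 0), pixel
counts and a square pixel size. The goniometer is a single fixed
rotation axis (unit vector), and the scan is a contiguous sequence of
equal-width frames (φ_start, Δφ, n_frames). Default fixtures place the
axis along +x and the beam along +z, but nothing in the code assumes
this.

Conventions, chosen once and used consistently by the simulator and the
indexer:

- 0-based pixel indices; the continuous pixel coordinate *p* maps to
  (*p* + 0.5)·pixel_size mm, so integer *p* is the centre of pixel *p*.
- The frame coordinate *z* is continuous from the scan start;
  φ(*z*) = φ_start + *z*·Δφ. A centroid in the middle of frame 0 has
  *z* = 0.5. Frame *f* covers *z* ∈ [*f*, *f*+1).
- Angles are degrees at every public interface, radians internally.
- The orthogonalization matrix **B** follows the Busing–Levy convention
  (a\* along lab x, b\* in the x–y plane); **B**ᵀ**B** equals the
  reciprocal metric tensor and det **B** = 1/V. The orientation **U**
  absorbs everything else, so the convention is unobservable.

Centroid → reciprocal space: pixel → mm (affine), mm → **s**₁ (lab
position normalized to length 1/λ, i.e. projected onto the Ewald
sphere), **r**_φ = **s**₁ − **s**₀, and **r** = **R**(−φ)**r**_φ. In the
noise-free case this chain inverts spot prediction exactly (round-trip
residuals ~1e-16 1/Å in the tests).

## Spot simulator

The simulator is the package's ground-truth instrument. For each
crystal it enumerates all Miller indices with ‖**A h**‖ ≤ 1/d_min and
solves the reflecting condition ‖**R**(φ)**A h** + **s**₀‖ = 1/λ in
closed form (the condition reduces to a cos φ + b sin φ = c, giving at
most two crossings per revolution); crossings inside the scan whose
scattered ray hits the panel become spots. Gaussian noise of configurable
sd (default 0.3 px in x/y, 0.3 frames in z) perturbs the centroids, and
the variances used are recorded in the spot table — they are the
refinement weights downstream. Multi-lattice tables are the shuffled
union of per-crystal lists plus optional uniform-random spurious spots;
hidden `true_*` columns keep the ground truth for scoring and are never
read by the indexing code.

Default study conditions mirror a narrow-wedge microcrystal experiment:
λ = 0.97949 Å, 214 mm distance, 0.1° frames, a PILATUS-6M-like panel
(2463×2527 px of 0.172 mm), cubic a = 100 Å cell, d_min = 4 Å (~370
spots per lattice per degree). What the simulator does *not* model:
pixel-level images and profiles, partiality/mosaicity of the centroids,
background (and hence intensity-error inflation), radiation damage, or
correlated spotfinding errors. Passing tests therefore demonstrate the
geometry, search, assignment and refinement machinery under realistic
centroid noise — not robustness to profile-level artefacts of real
images.

## Basis search

F(**x**) = Σ cos 2π(**r**ⱼ·**x**) is evaluated by direct summation over
directions sampled quasi-uniformly on a hemisphere (rings of constant
polar angle, azimuthal step scaled by 1/sin θ; the equatorial ring spans
half a turn so no two samples are antiparallel). An FFT evaluation would
give identical results; at these problem sizes (~3·10⁴ directions ×
~2·10³ reflections) direct summation is a single chunked matrix product
and takes well under a second.

- `angular_spacing` = 0.015 rad by default. The F-peak around a true
  axis has angular width ~d_min/(2π·a), so sampling cannot be expected
  to hit the summit; it only needs to land inside the basin that
  assignment-plus-refinement converges from. 0.015 rad (worst-case
  direction error ~0.43°) satisfies this with margin for the default
  conditions; very large cells with very high-resolution data would need
  a finer spacing.
- Candidates within `collinearity_angle` = 5° (parallel or antiparallel)
  of a higher-scoring candidate are dropped; the top 30 survive.
- Ordered candidate triples (with sign choices — the hemisphere sees only
  one of ±**x**) are matched against the target cell within
  `rel_length_tol` = 0.10 and `abs_angle_tol` = 5°, inverted to setting
  matrices, and scored by the number of reflections they index at
  `hkl_tolerance` = 0.3. Triples with volume below 10% of the target
  cell volume are rejected as degenerate; left-handed triples are fixed
  by overall inversion. The indexed-count metric is deliberately simple;
  ties go to the smaller mean ‖**h**′ − **h**‖.
- The search expects the primitive-setting cell. A helper converts
  common centred settings (I, F, A/B/C) to primitive via the metric
  tensor; converting results back is the caller's concern.

## Assignment and outlier handling

**h**′ = **A**⁻¹**r**; a reflection is indexed when ‖**h**′ −
round(**h**′)‖ < 0.3, and with several lattices it goes to the lattice
minimizing that residual (the comparison is made in hkl space). Two
reflections may not hold the same (lattice, **h**): the smaller residual
wins (ties broken by spot id, which also makes the whole pipeline
invariant to row order), the rest are flagged outliers. A separate
positional filter flags assignments whose predicted centroid deviates
from the observation by more than 3 px in x or y or 2° in φ — the
XDS-equivalent defaults. Unassigned and outlier are distinct states:
unassigned reflections feed the next lattice search, outliers do not.

## Refinement

The objective is the weighted sum of squared discrepancies between
observed centroids and predicted central impacts, with residuals in
(x_px, y_px, φ_deg) and weights 1/variance per component (variances
floored at 1e-6 so noise-free data keeps finite weights). Per crystal
the parameters are a 3-component axis-angle update to **U** plus the
free cell parameters of the target cell's crystal system (1 for cubic
through 6 for triclinic); **U** is re-orthonormalized by construction
(the update is applied as a rotation), so det **U** = +1 always holds.
Beam and detector are held fixed by default — a 1° wedge cannot
meaningfully constrain them, and refined geometry is better imported via
the geometry file. Joint refinement concatenates all crystals'
parameters into one damped least-squares problem; with the geometry
fixed the per-lattice blocks are separable, which the tests verify.

The solver is `scipy.optimize.least_squares` (trust-region reflective
with Levenberg-style damping, 2-point Jacobians) with a **soft-L1 loss**
at f_scale = 3 on the weighted residuals. The robust loss matters while
peeling off the first of several equally strong lattices: at tolerance
0.3 roughly 20% of the *other* lattices' reflections chance-index
against any trial basis, and a plain quadratic loss lets this
contamination drag the fit off the true solution before positional
outlier rejection can act. Correctly assigned reflections have weighted
residuals ~1, deep inside the quadratic regime, so on clean data the
robust loss changes nothing. Convergence follows the scipy criteria
(ftol 1e-6, xtol 1e-8, capped iterations).

## The multi-lattice loop

Repeat: map currently unindexed, non-outlier reflections to reciprocal
space; search for a basis; take the candidate indexing most of them;
re-assign *all* reflections across all lattices found so far; refine
jointly and reject positional outliers (3 macro cycles); accept or
reject the new lattice. Stopping rules, with defaults chosen where the
method description gives none:

- stop when fewer than max(`min_spots_per_lattice` = 20, 5% of all
  spots) unindexed reflections remain, when no candidate basis is
  consistent with the cell, when the best candidate indexes fewer than
  `min_spots_per_lattice` new reflections, or at `max_lattices`;
- a lattice whose refinement fails to converge, or which retains too few
  reflections after outlier rejection, is discarded and the loop ends;
- **quality gate:** a new lattice is also rejected when its
  post-rejection rmsd exceeds half the outlier limits (1.5 px / 1°).
  A genuine lattice explains its reflections at the centroid-noise level
  (~0.3 px), far inside the limits, while a "lattice" assembled from
  chance-indexed spurious spots shows rmsds near the limits themselves
  (uniform residuals truncated at the rejection thresholds). This gate
  is what turns a pure-noise input into a clean failure instead of
  phantom lattices.

If no lattice at all survives, the driver raises with diagnostics (spot
count, search scores) rather than returning an empty success.

## Overlap analysis

The profile model is a Gaussian in a local frame per reflection: two
directions spanning the Ewald-sphere tangent plane at **s**₁ (sd σ_b,
the effective beam divergence, degrees) and the rotation direction (sd
σ_m, the mosaic rocking width, degrees), truncated at N_σ standard
deviations. The bounding box maps the ±N_σσ_b corner directions to
panel impacts and takes the enclosing integer pixel box; the φ
half-width is N_σσ_m exactly (no 1/|ζ| Lorentz inflation near the
rotation axis — a deliberate simplification of the full XDS-style
model, adequate away from the blind region). Boxes are half-open, so
face-sharing boxes do not overlap. A voxel (pixel × frame) is peak iff
its centre's scaled displacement lies within the N_σ ellipsoid; the
voxel containing the predicted centroid is peak by definition, which
also covers the degenerate σ → 0 limit. Candidate pairs come from one
k-d-tree query on box centres with a radius bounding any possible
intersection, then exact interval checks; a pair is a confirmed overlap
iff at least one voxel is peak in both masks. Both stages are verified
against brute-force oracles. Per-resolution-bin overlap fractions count
reflections involved in ≥1 confirmed overlap; empty bins are reported as
absent, not zero.

## Indexing-ambiguity resolution

For two-mode lattices (identity plus one reindexing operator, e.g.
(h,k,l) → (k,h,−l) for the *I*23 family) the pairwise Pearson
correlation of merged intensities on shared symmetry-unique indices is
computed under each relative reindexing; pairs sharing fewer than
`min_common` = 3 reflections get weight zero. Each dataset is embedded
as a 2-vector **x**ᵢ by minimizing Σ wᵢⱼ(**x**ᵢ·**x**ⱼ − ccᵢⱼ)² with
gradient descent under backtracking line search (objective provably
non-increasing), keeping the best of 100 seeded random restarts; the
embedded directions are split into two clusters (k-means on the unit
vectors). Labels are meaningful up to a global swap — the gauge symmetry
of the problem. A disconnected correlation graph is labelled per
component with a warning. Four-mode ambiguities are out of scope: the
operator table would extend naturally, but the two-cluster split would
not.

## Diagnostics

The expected spot count per wedge is a Monte-Carlo over random
orientations of the predicted-spot count; since every non-blind
reciprocal-lattice point crosses the Ewald sphere exactly twice per full
turn, the mean is ≈ N_sphere · 2·wedge/360°, which the tests confirm
within blind-region and panel-edge losses. The ratio of found spots to
this mean approximates the number of lattices present; a ratio above 1.5
raises the multi-lattice flag.

## Problem sizes and determinism

The test and acceptance workloads use 1° wedges (10 × 0.1° frames) at
d_min = 4 Å — about 370 reflections per lattice, 2200 for six lattices —
and a single 0.1° frame at d_min = 3 Å (~500 reflections) for the
single-image case; ambiguity fixtures use 50 datasets of 150
observations. Every random draw (orientations, noise, spurious spots,
intensity tables, embedding restarts) flows from an explicit integer
seed, and all outputs are bit-reproducible for a fixed seed.

## Known limitations

- Single-panel detectors only; no distortion, parallax or polarization
  corrections.
- The known unit cell is required: this is the known-cell search, not
  general-purpose 1-D/3-D FFT indexing.
- Beam/detector parameters are not refined (flag exists for joint
  orientation refinement only); import refined geometry instead.
- The candidate-basis metric (indexed count) can in principle prefer a
  sublattice or supercell setting for pathological tolerance choices.
- Overlap masks subsample φ at one voxel per frame; sub-frame structure
  is not resolved.
- Ambiguity clustering supports exactly two modes.
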