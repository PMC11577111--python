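# Methods

`bodyatlas` implements a reference-based, unbiased atlas-construction pipeline
for whole-body MR-like volumes, together with the synthetic phantom cohorts it
is tested on. This note documents the models, the numerical choices, and what
the synthetic experiments do and do not demonstrate.

## Coordinate and transform conventions

All volumes live on axis-aligned regular grids; a voxel index `(i, j, k)` sits
at `origin + index * spacing` in millimetres. A transformation is stored as a
dense displacement field `u` on the *fixed* grid with `phi(x) = x + u(x)`
mapping fixed-space points into moving space. Warping is pull-back: the output
image on the fixed grid samples the moving image at `phi(x)` (linear
interpolation for intensities, nearest for raw label ids, linear on one-hot
indicators for probability maps). Out-of-domain intensity samples are filled
with 0 (background). When *fields* are sampled off-grid (composition,
inversion), displacements extend with their edge values rather than zero —
zero extension would fabricate a compressive boundary layer and spurious
folding.

Composition follows `compose(outer, inner)(x) = outer(inner(x))`, so
`warp(warp(m, outer), inner) == warp(m, compose(outer, inner))` up to
interpolation error. When the outer transform is affine the composition is
evaluated in closed form (no outer-field resampling error).

Field inversion uses the fixed-point iteration
`u_inv <- -u(x + u_inv(x))` (default tolerance 0.01 mm, 50 iterations) and
raises on non-convergence; the achieved residual is recorded on the result.
The inversion of the *total* (affine + deformable) field is used for
unbiasing, because the averaged fields include the affine stage.

Stationary velocity fields are integrated by scaling and squaring (default 6
squaring steps). Velocities are capped so the scaled step stays below 0.4
voxel, a sufficient margin against folding in practice; every integrated field
in the randomized test suite has folding ratio 0.

## Synthetic phantom cohorts

The generator emulates the study conditions of a sex x BMI partitioned
whole-body cohort at desk scale:

* **Geometry** — 64 x 48 x 96 voxels at 3 mm (a ~19 x 14 x 29 cm torso), an
  ellipsoidal body (semi-axes 80/60/135 mm), a 12 mm subcutaneous-fat shell,
  six random visceral-fat blobs, and five disjoint "organ" ellipsoids (liver,
  spleen, pancreas, two kidneys) validated for pairwise disjointness and
  containment.
* **Intensities** — water-contrast-like: lean tissue 0.55, fat 0.25, organs
  0.75–0.85, background exactly 0; Gaussian acquisition noise (sd 0.02) is
  added *in subject space after* the ground-truth deformation, so all images
  share the same noise statistics. (Adding noise before warping smooths it
  differently per subject and makes masked intensity normalisation
  asymmetric between template and subjects — a failure mode we observed,
  not a hypothetical.)
* **Deformations** — per subject, a random smooth stationary velocity (white
  noise convolved with a 30 mm Gaussian kernel, scaled to max 8 mm,
  zero-tapered at the domain edge) integrated to a diffeomorphism, composed
  with a global isotropic scale (0.94–1.06) and translation (+-6 mm) about the
  grid centre. Every sampled deformation is checked to be folding-free and is
  exact ground truth for registration tests.
* **Phenotypes** — BMI uniform within the requested group's range, heights
  and body-fat models per sex, all health flags false unless the subject is
  generated as "diseased".
* **Planted disease effect** — diseased subjects convert an extra fraction
  (default +0.30) of lean voxels to visceral fat inside a known perirenal
  region; all subjects get a 0.05 baseline conversion over the abdomen so
  between-subject fat variance exists everywhere.

What passing tests on phantoms do **not** show: robustness to bias fields,
Dixon fat/water separation artefacts, station-stitching seams, breathing
motion discontinuities, or true anatomical shape variation beyond smooth
diffeomorphisms of a common template. Real-data hyperparameters will differ.

## Pre-processing

Min–max normalisation, percentile contrast windowing (default 1–99), body
masking and COM/ICP initialisation. Two numerical choices matter:

* Intensity statistics are computed on the body mask **eroded by 2 voxels**.
  Partial-volume voxels on the body boundary of a resampled image span the
  whole background-to-tissue range; including them makes the minimum and
  low percentiles of fixed and moving images incomparable.
* In-mask intensities are mapped to `[0.02, 1]` (background stays exactly 0).
  The gap makes the automatically generated mask reproducible, and with
  discrete percentile estimators the whole pipeline is idempotent to 1e-6.

The mask itself is the zero-background support when more than 20% of voxels
are exactly zero (phantoms; already-masked images); otherwise a multi-Otsu
lowest threshold (4, falling back to 3, classes) — a single Otsu split can
land on the fat–lean boundary and cut away the subcutaneous shell. ICP
refinement uses symmetric nearest-neighbour correspondences on 6-connectivity
surface voxels; its angular resolution is limited by surface voxelisation
(sub-degree recovery needs ~1 mm voxels on anisotropic shapes; on a smooth
near-ellipsoidal body at 3 mm the rotational signal is sub-voxel).

## Registration

Stage 1 is a 12-dof affine (translation, Euler rotations, log-scales, shears,
parameterised about the fixed-image centre) optimised with Powell's method
over a factor-4/factor-2 pyramid on the chosen metric (NCC by default; SSD and
a 64-bin partial-volume NMI with analytic gradients are available). The best
iterate is returned, so the final metric never exceeds the initial one.

Stage 2 is the diffeomorphic free-form deformation: a stationary velocity
parameterised by cubic B-spline coefficients on control lattices of 32/16/8 mm
over a 3-level factor-2 image pyramid. Because the grid is axis-aligned,
interpolation from lattice to dense field is a separable product of small
per-axis basis matrices; the metric gradient is pulled back to the
coefficients with the exact adjoint of that map. The gradient through
scaling-and-squaring is approximated by its small-deformation limit — a
standard approximation — while the backtracking line search always evaluates
the *exact* objective `D + lambda * BE`, so accepted steps are monotone by
construction. The bending energy is the mean squared second spatial
derivative of the dense velocity (self-adjoint zero-padded stencils), zero on
affine fields; `lambda` defaults to 1e-3. Each level's velocity initialises
the next, finer lattice by sampling at the new control points and spline
prefiltering. Iteration budgets default to 60/60/30; the optimisation is
fully deterministic (no stochastic sampling).

The phantom's textureless lean-tissue interior means the true deformation is
only identifiable near intensity edges; endpoint-error statements therefore
hold in the body interior on average, not voxel-wise in flat regions.

## Atlas construction and unbiasing

`A_init` is the voxel-wise mean of subjects warped into the reference space;
a coverage map (mean in-domain sampling weight) is exported so downstream
analyses can mask voxels with incomplete subject support. Label atlases
average linearly-warped one-hot structure masks into per-structure
probability maps in [0, 1]. Unbiasing applies the average of the inverted
total subject fields to the anatomical *and* every probability volume. For a
population of pure translations this reduces exactly to translating the
initial atlas by the negated mean translation, which the tests assert in
closed form; for one subject it is a two-interpolation round trip with max
interior error below 2% of the dynamic range on smooth images.

## Evaluation metrics

Dice (conventions: 1 when both masks empty, 0 when exactly one is), HD95 as
the max of the two directed 95th-percentile surface distances on
6-connectivity boundary voxels in physical mm (exact against an O(n^2)
oracle), and the folding ratio as the fraction of interior voxels with
non-positive Jacobian determinant (central differences scaled by spacing;
boundary excluded).

## Voxel-based morphometry

Atlas-space maps are Gaussian-smoothed (default FWHM = 2 voxels), a per-voxel
GLM with intercept + group indicator (optional covariates) is fitted, and the
group contrast's t statistic (pooled-variance two-sample t in the default
design) is mapped through the signed probit transform to a z score; positive
z means the pathological group exceeds the healthy one. Benjamini–Hochberg
FDR is applied over in-mask voxels and the significance mask additionally
requires corrected p < 0.001. Group sizes are balanced by seeded subsampling
of the larger group. Zero-residual-variance voxels get z = 0 and are counted.
Null calibration (average false-discovery proportion <= q within Monte-Carlo
error over 200 replicates) and planted-effect sensitivity (>= 70% of the
planted perirenal region at n = 15 vs 15) are asserted in the test suite at
small grid sizes chosen for runtime, not statistical necessity.

## Known limitations

* ICP initialisation cannot resolve rotations whose surface-normal signal is
  below one voxel (smooth convex bodies at coarse spacing).
* The affine metric is optimised derivative-free; with very flat NCC
  landscapes (feature-poor images) Powell can terminate at coarse precision.
* Bending-energy regularisation is global; regions of genuinely different
  stiffness (bone vs bowel) are not modelled.
* The NMI gradient assumes the linear partial-volume binning; histogram-bin
  boundary effects make it noisier than NCC on small volumes.
* No 2D support, no time-varying velocity fields, no GPU path.
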