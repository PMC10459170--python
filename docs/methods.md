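# Methods

## Problem setting

A monocular SLAM system reconstructs an endoscopic scene — organ surfaces,
soft tissue, instruments — as a 3D point cloud that is correct only up to an
unknown global scale: without extra metric information, no length in the
cloud corresponds to a physical length. `endoscale` recovers that scale from
calibration objects, applies it, and quantifies how accurate the resulting
metric reconstruction is. It works entirely on point clouds and manually
identified 3D picks; the SLAM front end (images, features, tracking) is out
of scope, as is camera intrinsic calibration — nothing downstream of the
cloud consumes intrinsics.

Throughout, the scale factor is defined as

    s = d′ / d,

the ratio of a reconstructed length d′ to its real metric counterpart d
(reconstructed-over-real). Recovering metric units therefore *divides*
coordinates by s. Clouds carry a unit tag (`mm`, `cm`, `m`, or `arbitrary`
for scale-ambiguous reconstructions); the canonical internal unit is the
millimetre, since the physical ground truths in this domain (lesion lengths
of order 20–40 mm, calibrator squares of 24 mm, box plane separations of
tens of mm) are naturally quoted in mm. The `arbitrary` tag doubles as a
pipeline guard: arbitrary clouds cannot be unit-converted or ICP-aligned,
and metric clouds cannot be rescaled twice.

## Scale recovery

### In-scene calibrator

An object of known dimensions co-reconstructed with the scene yields pairs
(d′ᵢ, dᵢ) of reconstructed and real feature lengths — e.g. neighbouring
corner distances of a checkerboard of known square size, or the length of a
surgical instrument. Each pair gives a ratio sᵢ = d′ᵢ/dᵢ. With several
pairs, the aggregate is their **geometric mean**: it is the estimator
symmetric under inverting the ratio's orientation (the geometric mean of
d′/d is exactly the reciprocal of the geometric mean of d/d′), which an
arithmetic mean is not. The coefficient of variation of the per-pair ratios
is reported as a fit residual; a large value signals an inconsistent
calibrator (misidentified corners, strong local distortion). Corner/feature
3D coordinates are assumed already identified in the cloud (manual picks or
synthetic labels); image-space corner detection is out of scope.

### Pre-calibration box

When no calibrator can enter the cavity, the endoscope passes through a
calibration box before insertion. Its top and bottom inner walls are
parallel planes whose physical separation is measured conventionally.
Candidate wall points are selected from the reconstructed box interior and
the two planes are fitted **jointly under a shared-normal constraint**:

    argmin_{n, d₁, d₂}  Σᵢ (n·pᵢ + d₁)² + Σⱼ (n·qⱼ + d₂)²,   ‖n‖ = 1.

This has a closed form. For fixed n the optimal offsets are set by the wall
centroids, d_k = −n·c_k; substituting them reduces the objective to
nᵀ(S₁ + S₂)n, where S₁, S₂ are the centered scatter matrices of the two
point sets, so the optimal shared normal is the eigenvector of S₁ + S₂ with
the smallest eigenvalue, and the residual sum of squares *is* that
eigenvalue. The closed form is exact and deterministic; a test keeps the
literal least-squares objective authoritative by checking the eigen
solution against an independent general-purpose numeric minimizer on seeded
noisy instances (agreement ≤ 1e-6 relative demanded; observed ~1e-12).

If the two smallest eigenvalues coincide within 1e-12 (relative to the
largest), the shared normal is not identifiable — both sets collinear, or
isotropic scatter — and the fit raises an error rather than picking a
direction arbitrarily.

Since the fitted normal is unit, the reconstructed plane separation is
|d₁ − d₂|, and s = |d₁ − d₂| / true separation.

**Iterative reselection.** Real wall selections are contaminated by side
walls, markers and noise, so selection and fitting alternate: the first
pass selects by axis-aligned region only; subsequent passes additionally
keep only points whose stored normal lies within a cone (default 25°,
sign-ignored — opposite walls face each other) of the current fitted
normal, and drop residual outliers beyond 3× the robust spread
(1.4826·MAD, centered on the median residual so that an offset bias in the
previous fit does not evict an entire wall). Iteration stops when the fit
objective changes by less than `tol` (default 1e-10) or after `max_iter`
(default 10) passes; `max_iter=1` reduces exactly to the single-pass fit.
The 25° cone and the 3×MAD gate are conventional robust-statistics defaults,
both overridable.

Convergence is declared when the objective stalls below `tol` or the
inlier selection reaches a fixed point. Like any iterative trimming
scheme, the reselection can enter a limit cycle in which one or two
boundary points flicker in and out of the inlier set; in that case the
estimator returns the final fit flagged `converged=False` (the scale
estimate is typically still accurate — the flicker moves the fitted
offsets by a fraction of the noise level).

Plane normals are canonicalised (unit norm, K ≥ 0, ties broken J ≥ 0 then
L ≥ 0) so independently fitted planes compare stably across runs.

## Local conformity evaluation

The clinically relevant accuracy is local: does a target feature (a lesion,
a marked span of tissue) measure correctly in the metric-scaled cloud? The
feature's endpoints are picked manually N times (repeated picks absorb both
reconstruction noise and picking variability); each trial's length Dᵢ is
the Euclidean distance between its endpoints, compared to the physically
measured truth D^gt:

    RMSE  = √( Σ (Dᵢ − D^gt)² / N )                 [mm]
    rel.  = √( Σ rᵢ² / N ),  rᵢ = 100·|Dᵢ − D^gt|/D^gt   [%]

The relative statistic is the RMS of per-trial relative errors; with a
single shared truth it equals 100·RMSE/D^gt identically, and the identity
is asserted in a property test (the two published phrasings coincide up to
their pre-rounding). All statistics are computed at full precision;
rounding (half-to-even, 2 dp) happens only at the display layer.

Endpoint picking is input, not computation: picks arrive via the
measurement config (YAML/JSON) or synthetic labels. No saliency-based
auto-picking is attempted.

**A note on the published worked example.** The transcribed five-trial
lesion table prints endpoint coordinates rounded to 3 dp (cm) next to
distances at 2 dp (mm). A ±0.0005 cm quantisation on six coordinates can
shift a distance by up to ~0.017 mm, and one row indeed disagrees with its
own coordinates by exactly that much (38.69 printed vs 38.71 recomputed).
The recomputed aggregate statistics land within the same envelope
(3.00 mm / 8.31 % vs the printed 2.99 mm / 8.30 %). Tests assert exact 2-dp
reproduction for the four self-consistent rows, the quantisation envelope
for the fifth, and exact reproduction of the aggregate statistics from the
printed distance series.

## Global accuracy evaluation

When a metric reference cloud exists, the metric-scaled reconstruction is
rigidly aligned to it with classic point-to-point ICP (nearest-neighbour
correspondences via a KD-tree, gated at a maximum correspondence distance;
rigid step solved by SVD of the cross-covariance with the reflection case
corrected to keep det R = +1), then each reconstructed point's distance to
its nearest reference point is collected and summarised (RMSE, mean, max).

Choices and their rationale:

* **Direction fixed reconstructed → reference.** Robust to holes and
  dropout in the reconstruction (missing points contribute nothing);
  deliberately blind to coverage. Symmetric Hausdorff/Chamfer variants are
  excluded.
* **Correspondence gate** defaults to 5× the median nearest-neighbour
  spacing of the reference — wide enough not to starve a mildly misaligned
  cloud, tight enough to shed gross outliers.
* **Monotone residual trace.** With a gate, a textbook ICP step can in rare
  cases raise the mean residual (the correspondence set changes); the
  implementation rejects such a step, keeps the previous transform and
  stops, so the recorded trace is non-increasing by construction.
* **No scale in ICP.** Scale must already be recovered; a unit-tag guard
  enforces the stage ordering.
* Initialisation is the identity, or a coarse rigid fit from ≥ 3 manual
  correspondence pairs.

No numeric global-accuracy reference value exists for the physical
experiments this package models (no reference scan), so the global module
is validated by construct-and-recover properties: a rigidly displaced copy
aligns back to < 1e-6, KD-tree distances equal an O(N·M) brute-force scan,
Gaussian-noise clouds score an RMSE inside (0, 2σ), and 30 % dropout moves
the RMSE by < 10 %.

## Synthetic scenes

The generator provides the three fixtures every pipeline stage needs, with
exact ground truth and seeded determinism (same config ⇒ bit-identical
clouds on one platform):

* **Box interior** — four walls (top/bottom parallel pair at the configured
  separation, default 60 mm; two side walls), uniformly sampled at a
  configurable density with inward wall normals and per-point wall labels.
* **Grid calibrator** — an r×c corner lattice (default 9×7, 24 mm spacing);
  returns the degraded corner cloud and all surviving horizontal/vertical
  neighbour (reconstructed, real) length pairs.
* **Organ surface** — the upper hemisphere of an ellipsoid (default radii
  45/35/30 mm) displaced along its normal by a sinusoidal wrinkle field
  (default amplitude 1.5 mm, angular frequency 6) — the simplest surface
  with the qualitative character of wrinkled soft tissue; two lesion
  endpoints sit symmetrically about the apex at a chord distance solved by
  bisection to equal the configured true length (default 20.80 mm).

**Degradation** applies, in a fixed order: uniform scaling by the hidden
s*, a random rigid pose, isotropic Gaussian noise, uniform bounding-box
outlier injection, Bernoulli dropout. Scaling comes first so that the noise
σ is expressed in *reconstructed* units — the way noise presents in a real
monocular cloud, where the scale ambiguity precedes everything the
evaluator sees. Bookkeeping maps every degraded point back to its clean
source (outliers marked −1), so wall labels and corner identities survive
degradation. Organ lesion endpoints are carried through scale, pose and
noise but exempted from dropout and outlier accounting: they model *named
manual picks*, which an operator supplies regardless of local point
density.

What the generator does **not** emulate: structured SLAM error (drift,
locally correlated distortion, track-loss seams), view-dependent sampling
anisotropy, and textureless-region hole patterns. Passing recovery tests on
these scenes therefore demonstrates correctness of the estimators under
their stated noise model, not end-to-end fidelity on real endoscopic data.

## Numerical and design notes

* Plane-pair fit: eigen-decomposition of a 3×3 symmetric matrix
  (`numpy.linalg.eigh`); no iteration, no initialisation.
* Rigid fit: Kabsch/SVD; correspondences with a (near-)collinear source
  scatter (second singular value ≤ 1e-12 of the first) are rejected as
  degenerate rather than resolved arbitrarily.
* Nearest neighbours: `scipy.spatial.cKDTree`; ties resolve to the smallest
  reference index, making reports deterministic.
* PLY I/O is implemented in-package for the two dialects used (ascii 1.0,
  binary_little_endian 1.0, float x y z [nx ny nz]); ascii is emitted by
  default for diffability and the header records the length unit in a
  comment. Parse errors name the offending line or byte offset.
* Unit conversion multiplies or divides by the exact integer power of ten —
  never by an inexact reciprocal like 0.1.
* Simulation sizes in the test and acceptance runs (≈10³–10⁴ points per
  cloud, 50 synthetic boxes, 20 oracle instances) were chosen as the
  smallest sizes at which the measured quantities are stable to well within
  the asserted tolerances.

## Known limitations

* Single parallel-plane pair only; multi-box or non-parallel calibration
  geometries are unsupported.
* Scale is a single global scalar; locally varying (drift-induced) scale is
  neither modelled nor detectable by these tools.
* The wrinkle model is a smooth displacement field; it does not reproduce
  sharp folds, specular dropouts or vascular texture.
* Global evaluation reports accuracy only, not completeness.
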