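# Methods

`wsicoloc` maps point annotations between two whole-slide images (WSIs) of
the *same* physical tissue section — re-stained (e.g. H&E → IHC) and/or
re-scanned on a different device — with sub-pixel precision.  It follows
the colocalization philosophy rather than classical image registration:
instead of optimizing one transform that warps a whole image (and smears
residual error over regions that actually coincide), every annotation ends
up with its own locally estimated mapping.

## Model and procedure

The pipeline has three stages, each producing steps of an ordered
**transform chain** that is later applied to arbitrary point sets:

1. **Preprocessing.** A configured dihedral orientation op (one of eight
   right-angle rotations/flips) is applied to the fixed slide and its
   annotations to remove gross orientation discrepancies — these are not
   detectable reliably by intensity registration and are runtime
   parameters.  Tissue is then segmented on an overview level (Otsu
   threshold, dark-on-light; dilation, erosion, hole filling with a
   radius-3 disc) and filtered to the relevant particles; the tight union
   bounding box, slightly expanded, is the registration ROI.  A manual ROI
   override replaces the automatic one verbatim.
2. **Coarse stage.** The ROI overviews of both slides — read at the level
   `L` where `magnification / 2**L ≈ 2.5×` (80× → level 5, 40× → level 4),
   so that both overviews share approximately the same mpp — are
   registered with a four-parameter similarity transform
   `p ↦ s·R(θ)(p−c) + c + t` (center fixed at the ROI's geometric center),
   initialized by aligning geometric centers.  The estimate is then
   *extrapolated to the base layer*: translations and centers are
   multiplied by the overview downsample factors and composed with the
   ROI-offset translations; angle and scale are untouched (except that
   differing fixed/moving overview factors fold into the scale).  This is
   the only place level-scale conversion happens, which prevents silent
   double-scaling.
3. **Refinement.** Either
   *Strategy I* — a row-major grid of equal tiles over the fixed ROI;
   every tile containing an annotation is re-registered (rigid model by
   default) against its coarse-mapped moving region; or
   *Strategy II* — a small square patch (default 192 px, the center of
   the recommended 128–256 range) around every single annotation is
   registered with an affine correction.  In both cases the moving-side
   patch is sampled on the fixed patch grid *through* the coarse
   transform (bounding-box read with the coarse rotation compensated and
   the coarse scale absorbed in a single cubic B-spline resampling), so
   the refinement only sees the small residual.  A correction `C`
   estimated in the patch frame is lifted to moving base coordinates as
   `A = G·C·G⁻¹`, where `G(u) = T(o_f) + s·ds_f·R(θ)·u` maps patch pixels
   to moving base coordinates from the *actual* read-grid origin `o_f`.
   Getting this bookkeeping exact (read origins are rounded to the level
   grid; pixel centers sit at integers) matters: half-pixel convention
   slips here cost more than the entire registration error budget.
   Strategy II can optionally start from Strategy-I-refined coordinates
   (`strategy="1+2"`).

Applying the chain composes the steps in creation order — orientation op,
base similarity, then the tile correction whose fixed-frame rect contains
the original point (boundary ties go to the lower row-major index) or the
point correction matching the annotation id — and finally rounds
half-to-even to discrete target pixels.  Per-tile corrections can
alternatively be interpolated across tiles with a cubic B-spline fit of
the displacement sampled at tile centers (`smooth_tiles=True`); the
default treats tiles independently, since corrections are discontinuous
at tile borders either way and the spline needs a complete ≥4×4 tile
grid to be well posed.  Strategy-I chains are reusable for new point
sets; Strategy-II chains refuse unseen points, because a per-annotation
correction is meaningless anywhere but at its own annotation.

## Similarity metric and optimizer

Stain and scanner changes alter intensities non-monotonically, so the
metric is Mattes mutual information: joint intensity density estimated
with Parzen windows (zero-order kernel on fixed intensities, cubic
B-spline kernel on interpolated moving intensities; 32 bins with two
guard bins per side; intensity ranges taken from the whole images so the
binning is stable under transform changes), evaluated at random fixed-
domain coordinates (2048/iteration by default) and reported in nats,
negated for minimization.  With exhaustive sampling the value is
deterministic and equals a dense joint-histogram computation to ≤1e-6
nats — that equivalence is tested against an independently coded oracle.

Optimization is adaptive stochastic gradient descent: steps
`γ(t) = a/(A+t)^α` with `α=1`, `A=20`, the gain `a` auto-scaled from probe
gradients so the first step moves at most δ=1 scaled unit, and the
artificial time `t` adapted by a sigmoid of the normalized inner product
of successive gradients (anti-correlated gradients → larger `t` → smaller
steps).  Two departures from the textbook scheme proved necessary:

- **Step clipping.** Near the sharp MI peak the gradient grows by an
  order of magnitude; with the gain tuned for the flat far field the
  update would overshoot by several pixels and escape.  Steps are clipped
  to δ per iteration (infinity norm).
- **Deterministic polish.** After the stochastic phase at the finest
  level, the optimizer re-runs on one frozen, dense sample set
  (exhaustive when the image has ≤ `polish_samples` pixels) in two rounds
  with shrinking finite-difference steps.  This removes the residual
  sampling jitter; recovered transforms on constructed cases are accurate
  to ~0.02 px.

Gradients are central finite differences of the sampled metric with
common random numbers (the value and all probe evaluations share one
sample set, batched through a single interpolation call).  Parameters are
rescaled so one optimizer unit induces ≈1 px of motion at the ROI corner
(angle and scale entries divided by the half-diagonal), which is what
makes joint optimization of heterogeneous parameters stable.  The
registration runs over a Gaussian image pyramid coarse→fine
(3 resolutions, 500 iterations/level for the coarse stage; refinement
stages use 2 resolutions, 100–150 iterations and smaller sample budgets —
their inputs are already nearly aligned).  Angles are degrees,
CCW-positive in the y-down pixel frame; estimated transforms map fixed
coordinates into the moving domain — exactly the colocalization
direction, no inversion step.

## Synthetic data: what it emulates, and what it does not

The generator renders one tissue fragment (smooth blob with a noisy
boundary) with eosin-textured stroma and dark elliptical nuclei with
irregular borders on a white background, and derives the moving slide by
re-rendering the same geometry under an appearance model and resampling
through a composed mapping with exact closed-form ground truth:

    fixed p  →  + extent offset  →  dihedral op  →  global similarity
             →  + smooth local displacement  =  moving q

Emulated variation sources and defaults: stain change (H&E-like vs
IHC-like: hematoxylin counterstain on all nuclei, DAB-brown annulus on a
random 30 % of nuclei — the marker labels a minority); mpp ratio between
scanners (≈±10 %, folded into the similarity scale as `scale/mpp_ratio`);
scan-extent/base-coordinate offsets; global similarity misalignment
(scale constrained to [0.8, 1.25]); smooth local deformation as a
spline-interpolated Gaussian random field (defaults: amplitude 1.5 px
RMS, correlation length 200 px — minor re-staining tears/displacements
without topology breaks; amplitude > smoothness/2 is rejected as
folding); additive intensity noise.  All randomness flows through one
seeded generator per call; identical seeds give byte-identical slides.
No quantitative deformation magnitudes exist for re-staining damage in
the source data, so these defaults are declared, parameterized stand-ins.

Not emulated: realistic stain spectra and scanner color responses, focus
variation, tissue folds/tears that break invertibility, pen marks and
dust, and the sheer size and texture richness of clinical WSIs.  Passing
tests therefore demonstrate geometric correctness and stain-independent
convergence of the method under controlled, invertible conditions — not
robustness to every artifact class of clinical material.

## Evaluation

For synthetic runs the ground-truth map gives exact per-annotation
Euclidean errors (px, and µm via the declared mpp).  The photometric
protocol used when no ground truth exists extracts patches centered on
the mapped coordinates from every slide, covers the same physical extent
everywhere (patch dims set by the coarsest-mpp slide, default 256 px
there), rescales all patches to those dimensions, literally drops the
first and last rows and columns (absorbing uneven dims after resizing),
and computes grayscale SSIM (Gaussian window σ=1.5, width 11, K1=0.01,
K2=0.03 on the declared dynamic range — standard constants, exposed in
config) for every slide pair; the per-annotation minimum over pairs is
the headline statistic.  SSIM is computed on luminance.

## Numerical choices and degenerate inputs

- Coordinates: 0-based, x right / y down, pixel centers at integers,
  rectangles half-open; point discretization rounds half-to-even.
- Interpolation: cubic B-spline everywhere (pre-filtered coefficients,
  computed once per image); background fill 255 (white slide).
- Pyramid levels: Gaussian anti-aliasing (σ = 2/3 per halving) before 2×
  decimation; level dims `ceil(previous/2)`.
- Constant images yield MI = 0 with a warning; metric evaluations where
  fewer than 25 % of samples land inside the moving image raise an
  overlap error; registrations whose metric worsens three levels in a row
  return a failure status with the best-so-far parameters.
- Per-tile/per-point refinement failures (including corrections that
  would displace a patch by more than a quarter of its size — impossible
  given a sane coarse stage) never abort a run: the point falls back to
  the base transform and is flagged.  Losing annotations is worse than
  mapping some of them coarsely.
- Particle relevance filtering keeps particles with
  `area ≥ mean − k_a·std` and distance to the area-weighted mass center
  `≤ mean + k_d·std` (k_a = k_d = 1).  The comparisons carry a relative
  epsilon and a relative area floor (1 % of the largest particle)
  because the bare rule is degenerate for two-particle sets — the smaller
  particle lands exactly on the statistical boundary — and the filter
  must be idempotent and never empty (the largest particle is kept, with
  a warning, if everything fails).
- Strategy choice (`auto`) compares registered-pixel cost plus a fixed
  per-registration overhead (default 41 000 pixel-equivalents, fitted
  from observed per-tile vs per-patch throughput); purely advisory.

## Problem sizes used by the test suite

The published use case runs on multi-gigapixel scans; the test suite and
acceptance script exercise the identical code paths at desk scale, as the
package's own benchmark conditions: 1024² slides (150 nuclei) for coarse
parameter recovery across 10 seeds; one 1600² slide pair at a declared
0.25 mpp (similarity misalignment + 1.5 px smooth deformation + IHC
restain) with 100 clustered annotations refined by Strategy I (192-px
tiles, matching the patch scale at which the per-tile rigid model bounds
the residual of the coarse scale estimate) and 100 dispersed annotations
refined by Strategy II (192-px patches); 512² slides for unit tests.

## Known limitations

- Transform models are linear (rigid/similarity/affine); non-rigid
  deformation models are out of scope, so tissue damage beyond smooth
  low-amplitude deformation is only approximated patch-locally.
- Orientation discrepancies must be configured, not detected.
- Per-tile corrections are discontinuous at tile borders (unless the
  smooth-tile interpolation is enabled), and a rigid per-tile model
  leaves the coarse scale residual growing toward tile corners — the
  motivation for small tiles and for Strategy II where accuracy is
  critical.
- The overview-level rule assumes power-of-two pyramids; arbitrary
  per-level factors are supported in metadata but the rule clamps to
  available levels.
- Anisotropic mpp (x ≠ y) is carried as metadata and respected by the
  evaluation patch extraction, but registration treats pixels as square.
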