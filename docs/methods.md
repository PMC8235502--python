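# Methods

This note documents the definitions, parameters and numerical choices
behind `stilquant`, and what the synthetic fixtures do and do not show
about real slides.

## Coordinate and raster conventions

Rasters use 0-based pixel indices, x rightward and y downward; a point
(x, y) in pixel units measures distances to *pixel centers* (the center of
pixel (ix, iy) is the point (ix, iy)). Calibration is a single isotropic
scalar in µm/px; anisotropic pixel sizes are rejected at load time because
no downstream operator defines behavior for them. One pixel covers
(µm/px ÷ 1000)² mm².

A discretized disk of radius r contains every pixel whose center lies
within r (inclusive), so the 150 µm proximity rule reads "within". All
µm-parameterized operators convert through the calibration and are
scale-consistent: rerunning on a 2× upsampled raster with halved µm/px
changes derived areas by well under 2 %.

### Spatial operators

* **Disk-kernel fraction** — at each pixel, the fraction of true pixels
  within the disk, normalized by the number of disk pixels *inside the
  image* (no padding assumption), so tumor-fraction values near slide
  edges are unbiased. Implemented by FFT convolution with integer
  rounding; exact against a double-loop enumeration.
* **Dilation / erosion** — exact Euclidean operations via squared distance
  transforms (distances between pixel centers are square roots of
  integers, so thresholding on rounded squared distances is exact).
  Out-of-image pixels count as background, with one exception: the erosion
  half of a *closing* ignores the border, so closing is extensive
  (never removes pixels) even for objects near the slide edge.
* **Closing∘opening** — the macro-outline regularizer; as a composition of
  a closing and an opening it is idempotent. Note that an opening by a
  Euclidean disk rounds convex corners (a rectangle is *not* invariant);
  this is the correct behavior of the disk element, verified against the
  set-based oracle.
* **Point-to-mask distance** (`within_distance`) — exact
  point-to-pixel-center distances via a k-d tree on the true pixels, so
  boundary cases (149 vs 151 µm at a 150 µm threshold) resolve exactly.
  The TIL *filter*, by contrast, snaps each detection to its nearest pixel
  and reads the region masks there; sub-pixel snapping behavior is our
  choice, not guideline-mandated.

## Tumor-microenvironment geometry

Parameters (`GeometryParams`), all in µm where applicable:

| parameter | default | status |
|---|---|---|
| kernel_radius_um | 750 | fixed by the scoring protocol |
| tumor_fraction_threshold | 0.10 | protocol silent; our default |
| morph_radius_um | 250 | protocol names the operations, not the element; our default |
| margin_um | 250 | fixed (invasive margin) |
| epi_exclusion_um | 150 | fixed (epithelial buffer) |

The **macro-tumor** is {local tumor fraction ≥ threshold} under the 750 µm
kernel, closed/opened with the 250 µm element, intersected with tissue.
The 0.10 threshold was chosen so that satellite tumor nests within
~1.5 kernel radii merge into one macro region while an isolated single
gland (a few hundred µm²) does not clear the threshold; it is exposed in
configuration and recorded in every output's provenance. With no tumor
pixels the outline is empty and flagged; density computation refuses an
empty macro-tumor rather than returning 0.

The **invasive margin** is implemented as dilation of the macro-tumor mask
(not of raw tumor pixels), since the margin extends from the *outlined*
tumor border. The **tumor-associated stroma** is
(macro ∪ margin) ∩ tissue minus tumor, necrosis and non-invasive
epithelium.

The **exclusion zone** is tumor ∪ necrosis ∪ (non-invasive epithelium
dilated by 150 µm). A central hyalinized scar has no class of its own; a
segmentation backend must label it NECROSIS for it to be excluded. The
*scoring* stroma — the mask stored in `RegionPartition` and used as the
density denominator — is the tumor-associated stroma minus the exclusion
zone, so the TIL count (numerator) and stromal area (denominator) refer to
exactly the same region; the pre-exclusion stroma is kept alongside for
review. Excluded TILs carry audit codes with fixed precedence
IN_TUMOR > IN_NECROSIS > NEAR_EPI > OUTSIDE_STROMA, so reporting is
deterministic where zones overlap.

Invasive margin and central stroma are deliberately *not* scored
separately: the density is averaged over all tumor-associated stroma.

## Density and heatmap

Density is the kept-TIL count divided by the scoring-stroma area in mm²,
reported unrounded (display rounding happens only at the CLI, so cutpoint
comparisons never depend on formatting). The local-density heatmap uses a
200 µm circular kernel restricted to stroma, with the *disk∩stroma* area
as denominator — a full-disk denominator would underestimate local density
at stromal boundaries. Whether the kernel should be stroma-restricted at
all is a documented choice; we restrict it. Non-stroma pixels carry NaN.
The rendered PNG uses a fixed five-stop color ramp with values clamped at
the ramp maximum (noted in the legend) and is byte-deterministic.

## Backends

The three inference stages are contracts (`TissueDetector`,
`TissueSegmenter`, `CellDetector`); any conforming implementation can
drive the pipeline. The shipped reference backends invert the synthetic
renderer's color coding: tissue = chromatic distance from the background
color above 30 (8-bit RGB norm) with components < 0.01 mm² removed;
segmentation = nearest palette color (strict mode errors on unknown
colors, naming them); cells = connected components of cell-colored pixels
filtered by area ∈ [12, 120] µm² and circularity 4πA/P² ≥ 0.6, using the
Crofton perimeter (the contour-tracing perimeter degenerates on
1-px-thin components and would pass a thin bar). The area band brackets
lymphocyte size; none of the cell-level thresholds is guideline-fixed and
all are configurable. Pixels covered by rendered cells are attributed to a
configured tissue class (stroma by default), which is correct for the vast
majority of cells. The cell-level TIL class boundary (e.g. plasma-cell
inclusion) is carried as free text on the contract, not enforced.

## Serial-section registration

Annotation transfer between restained serial sections uses a 2×3 affine
fitted to ≥ 3 non-collinear landmark pairs by least squares, with
per-pair residuals and RMS reported in px (and µm when the target
calibration is supplied). No residual threshold is imposed — acceptance of
an alignment is the user's call. Dots mapped outside the target frame are
dropped and counted. Intensity-based and deformable registration are out
of scope.

## Survival statistics

* **Manual score handling** — per-block percentages are averaged over the
  available (1–2) tumor blocks; the manual dichotomization is
  strictly-greater at 10 %. The density dichotomization is ≥ at the
  selected cutpoint; the boundary rule is recorded in every output (the
  inclusive side at the density boundary is our choice).
* **Kaplan–Meier** — product-limit estimator (lifelines) with
  Greenwood-based confidence bands; tied events decrement the risk set
  simultaneously. Verified against explicit risk-set bookkeeping.
* **Log-rank** — hand-implemented signed standardized statistic with
  hypergeometric variance (needed in vectorizable form by the cutpoint
  search); χ²(1) two-sided p. Cross-checked against lifelines and a
  brute-force summation oracle.
* **Cox** — lifelines `CoxPHFitter` (Efron tie handling), complete cases
  only, Wald CIs. Continuous biomarkers enter scaled — manual/10,
  density/300 — so HRs refer to +10 % and +300 cells/mm² increments.
  Constant covariates are reported as HR 1 (flat partial likelihood)
  rather than failing; diverging fits (monotone likelihood; |coef| or
  se > 20 on the scaled covariates) raise an explicit error with the
  offending coefficients.
* **Maximally selected rank statistics** — candidates are the distinct
  biomarker values between the 0.10 and 0.90 quantiles (window
  configurable); for each the standardized log-rank statistic of the
  ≥/< split is computed in O(n) and the cutpoint maximizing |z| is
  returned. The adjusted p-value is the Miller–Siegmund
  improved-Bonferroni-type bound
  p ≈ 4φ(b)/b + φ(b)(b − 1/b)·log[ε₂(1−ε₁)/((1−ε₂)ε₁)] at b = max |z|,
  with ε the achieved low-group proportions at the window edges — flagged
  *approximate* (it is conservative for small candidate sets). An exact
  Monte-Carlo permutation p is available behind a flag (slower). The
  search runs on the raw cells/mm² scale; the /300 Cox normalization does
  not affect rank statistics.
* **Concordance** — sensitivity and specificity of the automated grouping
  with manual-high as the positive reference, plus a discrepant-case list
  flagging cases whose continuous scores lie within configurable bands of
  *both* cutpoints (default ±10 % manual, ±250 cells/mm² density) as
  expected cutpoint-neighborhood disagreement.
* **Endpoints** — overall survival (time to death, censored at last
  visit); relapse-free survival treats death without relapse as censoring,
  encoded in the cohort reader/generator.
* **Covariate codings** — age ≥50 vs <50 years, tumor size >2 vs ≤2 cm,
  nodes 0 vs 1–3 and 0 vs ≥4, tumor type ductal vs lobular and ductal vs
  other; derived reproducibly by `prepare_cohort`, which validates the
  schema and reports *all* violations at once.

## Synthetic fixtures

**Slides** (`SlideSpec`, default 4×4 mm at 2 µm/px): a stromal tissue
ellipse; tumor blobs built from overlapping disks with necrotic cores;
DCIS-like inclusions placed in stroma at a configured offset from a tumor
blob; TILs placed by a Poisson point process per compartment (stromal
default 600 cells/mm², the clinically relevant order of magnitude around
the 470 cells/mm² working cutpoint; optional left-to-right gradient
field), with decoy TILs inside tumor/necrosis and dense aggregates within
100 µm of DCIS to exercise the 150 µm exclusion; OTHER-class cells in all
tissue. Layering follows paint order STROMA < TUMOR < NECROSIS < DCIS
with those placement constraints, which keeps every morphology visible.
Cells render as 4 µm disks; an optional minimum-separation thinning
supports exact-count detector tests. Each cell is tagged with its true
compartment by direct mask lookup on the ground-truth partition —
independent code from the pipeline's filter, so their exact agreement is a
real check. Everything is a pure function of (spec, seed).

What the renderer does *not* emulate: H&E optics, stain variation, nuclear
texture, touching-cell morphology, scanner artifacts. Passing end-to-end
tests therefore validates the geometry, filtering, density and statistics
stages — not the segmentation/detection problem itself, which belongs to
the (pluggable) trained backends.

**Cohorts** (`CohortSpec`, default n = 257): log-normal sTIL density with
median ≈ 430 cells/mm² and σ_log = 0.8, so a cutpoint near 470 splits the
cohort roughly in half; exponential survival with hazard
h₀·exp(β·density/300 + covariate effects), with defaults β = ln 0.8,
h₀ = 7·10⁻⁵/day (OS) and 5·10⁻⁵/day (RFS), staggered uniform censoring
over 5.5–15 years — giving ≈ 49 % OS and ≈ 28 % RFS event fractions, the
regime of a long-follow-up TNBC cohort. A step-hazard variant places a
hazard change (default HR 0.45) at 470 cells/mm²; step-model simulations
use no covariate effects, isolating the two-group structure the cutpoint
search must find. Manual scores are generated per block as
density·(10/470)·lognormal noise (σ = 0.45), rounded to integers, with a
second block available 80 % of the time — linking 470 cells/mm² to the
10 % manual cutpoint scale and yielding realistic manual/automated rank
agreement. Degenerate specifications (no possible events) are rejected.

## Problem sizes and determinism

Tests run on reduced rasters (≈ 500² px slides, ≤ 128² oracle fixtures)
and on simulated cohorts of n = 150–2000 with 20–200 replicates; the
acceptance script uses one full-size slide (2000² px), 50 Cox replicates
at n = 2000 and 25 step-cohort replicates at n = 400. These sizes give
stable Monte-Carlo summaries while keeping a full run in minutes on one
CPU. All pipeline stages are deterministic given config + seed: reruns
produce byte-identical masks, JSON, CSV and PNG artifacts, and every
artifact embeds the configuration hash and input hashes.

## Known limitations

* No pyramidal WSI decoding, tiling, or out-of-core processing; rasters
  must fit in memory at one resolution.
* The reference backends key on renderer colors, not H&E appearance; real
  slides require trained backends implementing the stage contracts.
* The Miller–Siegmund bound is conservative; for small cohorts the
  permutation p-value is preferable.
* Invasive margin and central stroma are pooled by design; biomarkers that
  weight the compartments differently need a different partition.
* Competing risks, time-varying covariates and missing-covariate
  imputation are out of scope.
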