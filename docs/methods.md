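# Methods

## The measurement model

The package measures percent mammographic density (PD) with the
two-threshold semi-automatic procedure that underlies interactive density
tools. Its core assumption is that, after conditioning, pixel gray level is
a monotone proxy for tissue radiodensity, so two intensity thresholds
suffice: T1 separates air background from the imaged object, T2 separates
fat from dense tissue within the breast. PD is then pure pixel counting,

    PD = 100 * DT / (DT + FT),

evaluated as an exact rational in the pixel counts before conversion to
float. The procedure is *semi*-automatic by design: T1 is proposed
automatically (Otsu's criterion on the full image — the canonical
minimum-within-class-variance choice for a bimodal histogram; the proposal
function is pluggable) but can be overridden; T2 and the correction
strength α are operator choices; unwanted objects connected to the breast
are removed by explicit invalidation masks rather than by any automatic
detector. The session file consumed by the batch driver records exactly
these choices, so a run is fully reproducible from a flat text artifact.

Both threshold comparisons are non-strict (`>= T`): a pixel exactly at a
threshold is classified on the bright side. This is an arbitrary but fixed
convention; the alternative changes results only on measure-zero boundary
sets.

## Intensity conventions and ingest

All pipelines operate on float64 grids in [0, 1] with "brighter = denser".
PNG ingest divides by 2^depth − 1 (8- and 16-bit are both supported, since
conversion pipelines differ). DICOM ingest applies RescaleSlope/Intercept,
normalizes by the theoretical range implied by BitsStored, and inverts
MONOCHROME1 frames so the brightness convention holds everywhere
downstream. Coordinates are 0-based (row i, column j), row-major.

## The thickness correction

X-ray attenuation grows with both tissue density and tissue thickness.
Under compression the breast is near-uniformly thick except near the skin
line, where it thins and the image darkens; conversely a thick interior
region of fat can image as bright as dense tissue. The correction rescales
each breast pixel by

    K(d) = alpha + (1 - alpha) * d,      alpha in [0, 1],

where d is the *horizontal* (within-row) fractional distance from the
chest-wall reference to the breast edge: d = 0 at the reference column
(the image border on CC views; the per-row pectoral boundary on MLO views
when one is supplied), d = 1 at the outermost breast pixel of the row.
Rows whose edge coincides with the reference get d = 1. K is affine in d
with K(0) = alpha and K(1) = 1, so alpha = 1 is the identity (returned
bit-exactly, without touching the buffer) and smaller alpha attenuates the
interior more. The correction is multiplicative: "attenuation" of
brightness by a factor K <= 1 is a rescaling, not a subtraction, which
preserves the zero level and the monotone intensity-density relationship.

No physical thickness reconstruction is attempted — acquisition parameters
(compression force, kVp) are typically unavailable for screening archives —
and d is deliberately the simple row-wise proxy the correction formula
consumes, with no geodesic refinement. Default operation order is
stretch → segment → correct → classify; the histogram stretch uses
percentiles 1/99 of the *nonzero* pixels by default (robust to dead and
saturated pixels) and is configurable back to 0/100.

## Segmentation details

Foreground at T1 is labeled into connected components (8-connectivity by
default — robust to thin skin-line connections; 4 is available) and the
largest component by pixel count is the breast. Ties are broken
deterministically toward the component containing the smallest (row, col)
in lexicographic order. The pectoral muscle is handled as operator input
(an invalidation region or a per-row boundary), never auto-detected.

## Categorical scales

The Boyd scale has a dedicated "0%" category, so exact zero maps to it;
10, 25 and 50 open their bands (left-closed); 75 stays in 50–75, with
only values strictly above 75 in the top band. The generic cut-off binner
(`categorize_cutoffs`) is uniformly left-closed — a value equal to a
cut-off falls in the bin that cut-off opens, so quartile cut-offs
(7, 17, 29) give bins <7 / 7–17 / 17–28 / ≥29. The two conventions agree
everywhere except the special Boyd points 0 and 75; published reports do
not state how boundary values were assigned, so this package documents its
convention rather than inferring one.

## The phantom generator

The phantom emulates exactly the image properties the pipeline relies on,
with exact ground truth:

- **Geometry.** A half-ellipse breast flush against the chest-side border
  (vertical semi-axis 0.42·rows, horizontal extent 0.72·cols), 256×256 by
  default; MLO phantoms add a bright triangular pectoral wedge in the
  chest-side top corner together with its per-row boundary.
- **Intensity levels.** background 0.05, fat 0.45, dense 0.75. The ordering
  of contrasts mirrors real mammograms: the air/tissue gap (0.40) dominates
  the fat/dense gap (0.30), which is what makes a full-image bimodal
  threshold find the background/object split rather than the fat/dense one.
  Midway thresholds (T1 = 0.25, T2 = 0.60) separate the classes exactly on
  a noiseless image.
- **Dense tissue.** Random disks (radius 3 to rows/10) accumulated inside
  the breast until the target pixel count round(f · breast area) is
  reached; the last disk is clipped pixel-wise in raster order, so the
  achieved fraction is exact to the pixel. Exactness beats realism here:
  it turns end-to-end PD recovery into a sharp assertion.
- **Thickness falloff.** Breast pixels are multiplied by
  F(d) = a / (a + (1 − a)·d) with a = `edge_falloff_alpha`: full
  brightness at the chest reference, dimmed to a factor a at the edge.
  F is the algebraic inverse of the correction profile up to the constant
  a — F(d)·K(d) = a exactly — so correcting at matching α yields the clean
  image uniformly rescaled by α, never exceeds 1 (no clipping), and a
  single rescaled T2 classifies interior and near-edge tissue identically.
  A linearized dimming profile was considered and rejected because it
  makes the correction only approximately invertible and the
  misclassification-count assertions would need slack.
- **Artifacts and noise.** Bright rectangular labels are placed in disjoint
  row bands of the strip beyond the breast's horizontal extent (never
  touching the breast or each other under 8-connectivity); i.i.d. Gaussian
  noise (sd `noise_sd`) is added last and the image clipped to [0, 1].
  Identical spec + seed gives a bit-identical phantom.

What the phantom does *not* model: X-ray scatter, the heel effect,
parenchymal texture, skin-line airgap profiles, anatomical shape
variability, or vendor post-processing. Tests passing on phantoms
therefore demonstrate the pipeline's internal correctness (thresholding,
component selection, correction algebra, counting) — not clinical accuracy
on processed vendor images, which requires reader studies.

## Simulated raters

Repeated readings are modeled additively: rater r reads image t as
clip(PD_t + bias_r + N(0, sd_r), 0, 100). Under this model two raters with
equal noise sd sharing truth with variance s² have CCC = s²/(s² + sd²),
and the mean pairwise difference equals the bias difference — the closed
forms the calibration checks use (evaluated with the empirical variance of
the drawn truth sample). Clipping at the scale ends biases both slightly
when truth sits near 0 or 100; the default truth range (uniform 0–60,
matching screening-population PD) keeps that effect well inside the stated
tolerances.

## Agreement statistics

- **Lin's CCC** uses population (1/n) moment estimators,
  ccc = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²). The confidence interval is
  computed on the Fisher z scale with Lin's asymptotic variance and
  back-transformed; the method name is exposed as module metadata
  (`CCC_CI_METHOD`). Degenerate cases: both series constant → undefined
  (error); one series constant or |ccc| = 1 → the interval collapses to
  the point estimate.
- **Bland–Altman** differences are first-listed minus second-listed rater.
  Besides the classical limits mean ± 1.96·sd (for plotting), the summary
  reports the empirical 5th/95th percentiles of the differences, the
  dispersion measure conventional in density-reliability tables.
  Percentiles are numpy's default type-7 linear interpolation throughout.
- **Weighted kappa** uses quadratic agreement weights
  w_ij = 1 − (i − j)²/(k − 1)², with the Fleiss-Cohen large-sample
  standard error for the interval. If both raters are constant in the same
  category the chance-corrected statistic is undefined; the function
  returns NaN with a diagnostic warning rather than raising, since a batch
  run should report the degenerate pair, not abort.
- Missing readings are dropped pairwise with a logged count, so each pair's
  n mirrors what a per-comparison reliability table would report.

## Problem sizes and tolerances

Validation runs use 128–160 px phantoms — large enough that one pixel is
≲0.01% of the breast area, so sub-point PD tolerances are meaningful —
with 50-phantom sweeps for density recovery, 20 for the largest-component
rule, and n = 5000 simulated readings for the rater calibration (CCC
Monte-Carlo error ≈ 0.001, well under the 0.01 comparison band). The full
test suite and the acceptance script each complete in a few seconds on one
CPU.

## Known limitations

- No automatic pectoral-muscle or skin-line detection; MLO images need an
  operator-supplied boundary or mask, as in the interactive workflow.
- DICOM support is minimal (uncompressed monochrome pixel data, rescale
  and photometric attributes); compressed transfer syntaxes and
  presentation LUTs are out of scope.
- The Otsu T1 proposal assumes the air/tissue contrast dominates the
  histogram; on images where dense tissue dominates and background is
  small, the proposal may need operator override — which is exactly the
  semi-automatic contract.
- Agreement confidence intervals are large-sample approximations; for very
  small n a bootstrap would be preferable.
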