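# Methods

`pbmshape` implements a complete analysis chain for studying the shape of the
peripapillary Bruch's membrane (pBM) on radial optic-nerve-head OCT B-scans
and its association with intracranial pressure (ICP), together with a
synthetic cohort generator that provides ground truth for validating every
stage. This note records the models, conventions, parameter choices and known
limitations.

## Data model and coordinate conventions

A scan is a 2-D cross-section through the optic nerve head (ONH), acquired in
a radial pattern at six angles (0°, 30°, …, 150°), in both eyes, with lateral
scale 5.5–6.4 μm/px, axial scale 3.9 μm/px and width 1,024 px. Two raters
independently segment the pBM as two branches of per-column samples flanking
a discontinuity under the ONH.

* **Pixel traces** (`RaterTrace`) are in raster coordinates; axial y is
  stored vitreous-positive (larger y = deflection toward the vitreous). This
  is a file-format convention, chosen so that curve values, consensus curves
  and PC1 all share one interpretable sign: "positive = into the eye".
* **Canonical curves** (`PbmCurve`) are in microns and right-eye (OD)
  orientation. Left-eye (OS) traces are mirrored about the vertical image
  axis (x ↦ width − 1 − x, an involution) before scaling so temporal/nasal
  directions coincide across eyes.
* The consensus curve is the pointwise mean of the two raters, linearly
  interpolated onto the union of their sample grids. The outer end of each
  consensus branch is restricted to the raters' common support; the inner
  (margin) end extends to the union of their supports with endpoint-clamped
  interpolation over the few-pixel sliver segmented by only one rater. This
  guarantees the averaged margin annotation always lies on the consensus
  curve — otherwise the innermost semi-landmark (which *is* the margin) would
  be unplaceable whenever the raters disagree by even one pixel.

## Inter-rater reliability

The image width is divided into eight equal vertical segments (fixed image
geometry, not curve extent). A segment is flagged when the raters' axial
disagreement reaches 3 px (11.7 μm at 3.9 μm/px) at any shared column.
The cohort summary reports flagged proportions overall and for the two
central ("peripapillary") versus six outer segments, exceedance magnitudes in
px and μm, and a one-way ANOVA of per-scan flagged proportions across scan
angles (degenerate zero-variance inputs are reported as "no variation" with
F = 0, p = 1 rather than NaN).

## Synthetic cohort generator

The generator emulates the segmentation-level structure of such a study; it
does not synthesize raster OCT images. Per scan, the ground-truth curve is

    y(x) = s·d(x)/1000 + A·½(1 + cos(π·d(x)/1000)) · 1[d < 1000 μm] + ε(x)

where d is the outward distance (μm) from the pBM margin, s = −20 μm/mm is a
gentle outward baseline tilt, and the raised-cosine bump of span 1,000 μm at
each margin models vitreous-ward deflection. Its peak amplitude is

    A = gain(angle) · max(0, ICP − 20 cm H2O),

linear in the pressure excess over the upper normal bound, with an
anisotropic per-angle gain (default 2.0 + 1.0·sin²θ μm per cm H2O, maximal
for the vertical scan) because the ONH is not radially symmetric. No
published effect size exists for this relationship; the default magnitude
was chosen once as a realistic tens-of-μm deflection at clearly elevated
pressures and is fully tunable. ε is a smooth noise process (Gaussian knots
every 200 μm, linearly interpolated, sd 5 μm by default) representing true
anatomical variation shared by both raters.

ICP is drawn per subject from a three-component mixture matching the study
population this design emulates: normal (≤ 20), borderline (20–25) and
elevated (≥ 25 cm H2O) with weights 5/21, 5/21, 11/21 and uniform
within-category ranges (10–20, 20.5–24.5, 25–50 cm H2O). Truncated-normal
and uniform alternatives are available.

Raters re-trace the truth with independent per-column axial noise: sd
1.32 px in the two central image eighths and 0.59 px elsewhere, and margin
annotations jittered laterally with the central sd. These two defaults were
derived from the reported disagreement pattern of manual pBM segmentation
(roughly a third of central segments and ~4% of outer segments flagged at
the 3-px threshold) through the Gaussian exceedance probability of the
threshold, accounting for the fact that the ONH opening occupies most of the
central eighths so only a handful of central columns carry a curve. The
default cohort reproduces that pattern (≈11% of segments flagged overall,
≈31% central, ≈4% outer).

All randomness is stratified per (subject, eye, angle) from a single seed,
so cohorts are bit-reproducible and independent of generation order.

One geometric consequence of this model is worth stating plainly: the
deflection bump is margin-localized (peak at the margin, fully decayed
1,000 μm outward), while the distance-rule margins sit
1,612 μm from the scan center, i.e. roughly 860 μm outward of the true
margins under the default 750 μm opening half-width. Distance-strategy
landmarks therefore sample only the far tail of the modeled deflection and
carry much weaker ICP signal than user-strategy landmarks on synthetic
cohorts. In real eyes the vitreous-ward bowing extends much further from
the opening, which is why distance-defined margins classify well there;
emulating that would require a broader deflection model than the
margin-localized bump used here. Validation studies that exercise the
ICP signal consequently use the user-16 strategy.

What the generator does **not** model: optic-disc tilt, peripapillary
atrophy, axial-length effects, rater bias (noise is zero-mean), spatially
correlated rater error, or longitudinal ICP dynamics. Passing recovery and
calibration tests on these cohorts therefore shows the *pipeline* is correct
and well calibrated under its assumed data-generating model — not that real
OCT data satisfy those assumptions.

## Semi-landmarks

Four strategies: margins identified by the raters (`user`) or placed a fixed
1,612 μm from the optic nerve center (`distance`), each with 16 or 14 total
semi-landmarks. The optic nerve center for the distance rule is the scan's
lateral midpoint (scans are acquired centered on the ONH); the midpoint of
the user margins is available as a configurable alternative. The margin
itself is the innermost semi-landmark; the remaining seven (or six) per side
step outward at exact 180 μm lateral increments, y linearly interpolated
from the curve. Spacing is horizontal, not arc-length: segmentations are
y(x) functions per branch and the curves are shallow, so the two measures
differ negligibly; arc-length spacing was considered and rejected. The
14-point variants drop the *outermost* point per side, preserving the
margin, which carries the deflection signal. Placement is deterministic and
atomic: a landmark leaving the curve support excludes the scan for that
strategy (logged, not raised). At 5.5 μm/px a 1,024 px scan has a 2,816 μm
half-width, less than the 1,612 + 7·180 = 2,872 μm the distance-16 strategy
needs, so such scans are necessarily excluded — the geometric reason a
14-landmark variant exists at all.

## Procrustes analysis and shape PCA

Full generalized Procrustes analysis: configurations are centered, scaled to
unit centroid size, and iteratively rotated (SVD-based optimal rotation,
reflections disallowed) to the running consensus until the consensus RMS
change falls below 1e-10 (max 100 iterations; non-convergence is a logged
diagnostic, not an error). Because iterative superimposition only fixes the
aligned frame up to a global rotation, the output is anchored canonically:
the consensus' major principal axis is rotated onto the x-axis and, of the
two such rotations, the one keeping the right-hand landmark block at larger
x is chosen. This makes aligned coordinates invariant (to ~1e-7) under
arbitrary similarity transforms of the inputs and keeps the aligned y-axis
vitreous-positive.

Shape PCA is the eigendecomposition (via SVD) of the covariance of aligned
residuals about the consensus, flattened to 2k coordinates with the n−1
denominator; scores are residual projections, in dimensionless Procrustes
units. No semi-landmark sliding and no bending-energy weighting is applied,
and no tangent-space projection beyond residuals about the consensus — for
the shallow shape variation of pBM curves the curvature of shape space is
negligible at this sample size. PC1's sign is fixed so that a positive score
moves the two innermost semi-landmarks toward the vitreous (an exactly-zero
inner y-loading leaves the sign unchanged and sets a diagnostic flag); other
components keep the decomposition's stable order and arbitrary sign. Shape
spaces are built either over all scans (PC1_all) or per scan angle
(PC1_0 … PC1_150); angles with fewer than two configurations are skipped
with a warning.

## Statistics

* **ICP categories**: normal iff ≤ 20, borderline iff 20 < p < 25, elevated
  iff ≥ 25 cm H2O (boundary-exact).
* **GEE**: identity-link Gaussian GEE of eye-level PC1 on ICP with subjects
  as clusters and an exchangeable working correlation (independence
  available), via statsmodels. Robust standard errors use the Mancl–DeRouen
  bias-reduced sandwich, and the Wald statistic is referred to a t
  distribution with (clusters − 2) df: with 20–40 clusters the plain
  sandwich plus a normal reference is anticonservative, while this
  combination holds the 5% level (verified by simulation at 1,500
  replicates, rejection 0.044). Degenerate cases are resolved exactly:
  perfect linear fit → p = 0, constant response → slope 0, p = 1; constant
  ICP is a singular design and raises.
* **Repeated-measures ANCOVA** of PC1_all: classical split-plot strata.
  Within-subject effects are tested against their subject-interaction mean
  squares (angle: df 5, 5(s−1); eye: df 1, s−1 — exact under compound
  symmetry, which is the generator's own structure); the between-subject ICP
  covariate is tested against residual between-subject variation. Subjects
  with incomplete eye × angle tables are dropped (listwise); a
  Greenhouse–Geisser epsilon correction for the angle test is available by
  flag. A mixed-model formulation was considered and rejected: the variance
  component sits on the boundary under the null, making ML fits fragile and
  slow exactly where calibration must be verified.
* **ROC**: one eye per subject (right preferred by default; left-preferred
  and seeded-random rules available) so observations are independent.
  Empirical AUC with half-credit ties (normalized Mann–Whitney U), DeLong
  variance for the 95% CI (clipped to [0, 1]), operating points from
  scikit-learn's ROC curve. Dichotomies: elevated (≥ 25) vs rest, and
  normal (≤ 20) vs rest. No multiple-testing adjustment is applied to the
  per-angle analyses, matching per-angle reporting.

## Validation studies (evaluation module)

All replicate studies run the full pipeline (generator → canonical curves →
landmarks → GPA/PCA → statistics) unless noted, and are exactly reproducible
from a seed.

* **Recovery** — one 40-subject cohort (480 scans), noise sd 5 μm: oriented
  PC1 vs true bump amplitude, pooled (r_all ≈ 0.98) and per angle
  (min ≈ 0.97).
* **Coverage** — 200 replicates of a clustered linear model with known slope
  (40 subjects × 2 eyes, subject intercept sd 0.7, residual sd 1): robust
  95% CI coverage ≈ 0.95. Run at the score level because the pipeline-level
  true slope has no closed form.
* **Null calibration** — 1,000 zero-gain cohorts at the default size
  (21 subjects): GEE slope test and rmANOVA angle test each reject at ≈ 5%,
  and the elevated-vs-rest AUC at the vertical angle stays at chance.
* **Power/classification** — 100 default-gain cohorts of 40 subjects: every
  angle-specific PC1 reaches AUC ≥ 0.8 and GEE p < 0.005 in ≥ 90% of
  replicates (observed: all replicates, minimum AUC ≈ 0.97).
* **Anisotropy ordering** — with strictly increasing per-angle gains, the
  replicate-averaged mean |PC1| per angle reproduces the gain ordering.

## Numerical choices

GPA tolerance 1e-10 (consensus RMS change), max 100 iterations; orthonormal
components verified to 1e-8; eigen-ties broken by the decomposition's stable
order; zero centroid size raises; reliability segments are half-open
intervals over [0, width); segment ANOVA degeneracies reported, not raised;
all file formats are plain CSV/JSON/TPS text, read back with round-trip
float precision so files-mode reruns are bit-identical to in-memory runs.

## Limitations

Strictly 2-D (per-scan) shape; no 3-D ONH reconstruction. Exactly two
raters. No covariate adjustment (age, axial length, gender). The
ICP-deflection link is assumed linear above a hard 20 cm H2O threshold;
real pBM remodeling is likely smoother and history-dependent. Synthetic
conclusions transfer to real data only insofar as the generator's
assumptions (section above) hold.
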