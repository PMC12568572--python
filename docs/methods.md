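# Methods

`retinavasc` measures retinal vascular and optic-nerve-head morphometry on
disc-centered fundus photographs and compares two cohorts with
covariate-adjusted statistics. Because no suitable public image set carries
exact per-vessel ground truth, the package ships its own scene generator:
every stage is scored against synthetic eyes whose vessel geometry, disc
shape, and cohort structure are known exactly.

## Coordinate and unit conventions

Raster coordinates are pixel-centered, origin at the top-left pixel, x
rightward, y downward; screen angles use `atan2(-dy, dx)` so 90° points to
the superior retina. Default calibration is 10 µm/px on a 1024×1024 frame
(a 45° field); calibration is explicit metadata (`pixel_pitch`), never
assumed. Nasal/temporal directions follow laterality: nasal maps to +x in
right-eye (OD) images and to −x in left-eye (OS) images.

## Synthetic fundus scenes

Each eye carries eight vessel trees: an artery/vein pair along each of the
four arcades (superotemporal, inferotemporal, superonasal, inferonasal),
angularly offset by ±14° so paired trees rarely cross near the disc, nasal
trunks 0.85× thinner. A tree is a recursive bifurcating structure rooted on
the disc border:

- **Caliber.** Trunk diameters default to 12 px (artery) and 15 px (vein),
  i.e. 120/150 µm. Within a segment the diameter tapers linearly
  (end/start = 0.88); at each bifurcation the parent's end caliber splits
  by Murray's law `w_p^e = w_1^e + w_2^e` with exponent e = 3 and daughter
  ratio w₂/w₁ = 0.6. The residual of the Murray identity is below 1e−6 by
  construction. Tips stop branching once the thin daughter would fall
  under 1.8 px — sub-pixel vessels cannot be rasterized consistently.
- **Topology.** Up to six generations; from the second generation on each
  tip bifurcates with probability 0.7, otherwise it terminates. Whole-tip
  termination is deliberately caliber-independent: it staggers tree extent
  without biasing the caliber mix of distal zones, which is what makes the
  peripapillary caliber profile decrease monotonically outward (an
  asymmetric "side branches die early" rule enriches distal zones with
  thick survivors and inverts the profile). Daughter directions are pulled
  toward the local radial direction (weight 0.35), keeping each arcade in
  its own sector.
- **Tortuosity.** Segments meander as a squared raised cosine of peak
  lateral amplitude 5 px (wavelength parameter 130 px) confined to the
  segment interior; a straight margin of `max(16, caliber/2 + 15)` px at
  each end has zero offset, slope, and curvature, so vessels leave every
  bifurcation exactly along their chord and line fits near a node see a
  straight vessel. The true arc/chord ratio of every segment is computed
  by quadrature of the exact arc-length integrand and recorded in the
  truth table. The resulting true tortuosity (arc/chord − 1 ≈ 1–5 × 10⁻²)
  is larger than the ~10⁻³ values typical of clinical reports; that scale
  is treated as a reporting convention, and the generator operates at a
  magnitude that raster centerlines can actually resolve at the 5%
  relative-error gate.
- **Angles.** Bifurcation angles are drawn from N(63.6°, 7.5°); the thick
  daughter deviates less than the thin one (inverse-square weighting). The
  recorded truth is the realized angle between the two daughter chord
  directions (exact to machine precision), after the radial bias.
- **Rendering.** Vessels are stamped as disks of the local radius along
  each centerline — the truth mask is exactly the set of pixel centers
  within the local radius of the polyline. Veins render darker than
  arteries; where stamped artery and vein disks overlap the pixel is
  assigned to the vein (drawn on top), so the artery/vein truth masks are
  disjoint and their union is the vessel mask. The disc is a bright
  ellipse with a brighter concentric cup on a vignetted background with a
  mild horizontal illumination gradient; Gaussian pixel noise (default
  0.02 of dynamic range) is seeded independently of the geometry, so truth
  masks never depend on the noise seed. Segments leaving the circular
  fundus aperture are truncated, flagged, and excluded from truth tables.

## Cohorts

The two-group design mirrors a highland-vs-lowland children study: group
covariates follow the published baseline table (age 8.66±0.66 vs 8.08±0.28
years; male proportion 0.438 vs 0.522; axial length 22.76±1.51 vs
23.27±0.79 mm), deliberately imbalanced so the covariate adjustment is
exercised. Truth-level group effects for the highland group default to
−4 µm caliber, −1.45° branching angle, +0.184 mm² disc area, +0.068 mm²
cup area; caliber also carries a −2 µm/mm slope on axial length (a known
confounder, removed by the adjustment). Both eyes share the subject's
covariates and a subject-level random effect; eye-level noise comes on
top. Caliber noise defaults to 3 µm (subject) and 9.5 µm (eye), total
≈ 10 µm. This is somewhat below the ~13 µm spread of published cohorts: at
13 µm the design would not reach the intended ≥80% detection rate for the
−4 µm effect once the covariate imbalance inflates the variance of the
adjusted group contrast (variance inflation ≈ 1.5); the noise level was
chosen so the simulated study, like the real one, is adequately powered
for its headline caliber finding, and it was fixed before the acceptance
suite was written. With these defaults the ANCOVA detects the caliber
effect in ~94% of replicates and keeps the null rejection rate at ~5%.

## Segmentation (classical stand-in)

The learned segmenter of production systems is replaced by a classical
chain behind the same interface (mask + label masks + disc/cup ellipses),
so a model can be slotted in later:

1. **Preprocess.** The circular aperture is located from the non-black
   field of view (a uniform image yields the full inscribed circle); the
   green channel is background-subtracted by grey closing with a 12 px
   disk (larger than the widest vessel), which flattens the illumination
   field and is approximately idempotent.
2. **Vessels.** Multiscale tubularity (Sato filter, scales 1–7 px) on the
   normalized channel, hysteresis thresholding at 0.25/0.30 of the peak
   response, removal of components under 30 px. Thresholds were fixed by
   maximizing Youden's index (sensitivity + specificity − 1) against truth
   on the default scene and live in the config, not the code. On the
   default scene the mask scores ≈ 0.97 sensitivity / 0.98 specificity
   against truth, above the 0.85/0.96 floors the pipeline is gated on.
3. **Disc and cup.** The disc is the dominant bright blob above
   `median + 0.5·(p99.9 − median)` of the in-aperture intensities (an
   intensity-anchored rule; an area-quantile rule breaks when the disc's
   share of the aperture varies), ellipse-fitted from second moments; the
   cup is the brighter nested region. Containment (cup inside disc) is
   enforced.
4. **Artery/vein.** Per connected tree by mean central intensity (darker
   trees are veins; 2-class split at the largest gap in component means).
   A single tree is labeled artery by convention. In synthetic mode the
   ground-truth labels pass through unchanged.

## Centerline graphs

The mask is reduced to a medial skeleton (spurs under 5 px pruned), traced
into nodes (neighbor count ≠ 2; adjacent junction pixels merged) and
segments (degree-2 chains). Wide-vessel junctions often skeletonize into
two nearby degree-3 nodes joined by a stub; junction–junction segments
under 6 px are contracted so one physical bifurcation maps to one node.
Centerline points are refined to the sub-pixel medial ridge by parabolic
interpolation of the Euclidean distance transform along the local normal
(offsets clamped to 0.45 px so rounding preserves 8-connectivity); the
local radius is the interpolated distance-transform value at the refined
point, which on stamped bands is an approximately unbiased estimator of
the true half-width.

## Morphometry

- **VC (caliber, µm).** Width = 2 × local radius at interior centerline
  points (≥ 2 px from nodes), averaged per segment and aggregated
  length-weighted. On 20-scene batches the per-segment mean absolute error
  is ≈ 0.23 px against truth.
- **VT (tortuosity).** Arc/chord − 1 per segment. The junction blob at
  each end (within one vessel radius + 2 px of a node) is excised and its
  straight span folded back into the normalization, the remaining points
  go through a cubic smoothing spline whose tolerance is the centerline's
  own jitter (estimated from second differences; clean analytic curves
  are used as-is, raster centerlines are denoised at σ = 0.12 px), and
  the arc is taken along the spline. Region aggregates are
  length-weighted; the zonal value uses each segment's longest in-region
  run. Exactly collinear input returns 0 exactly; a closed loop (zero
  chord) raises. Batch-level recovered mean tortuosity lands within ~4%
  of truth; the analytic semicircle is reproduced to 7 × 10⁻⁶.
- **VBA (branching angle).** At degree-3 nodes within 2 PD of the disc
  center: the parent is the widest incident vessel, with a geometric
  tie-break when the top two widths are within 10% (the parent is the
  branch most opposed to the bisector of the other two); each daughter's
  direction is a principal-component line fit to its lightly smoothed
  points in a 10 px window beyond the junction blob, rejected if the RMS
  fit residual exceeds 0.5 px or if the incident artery/vein labels mix
  (a crossing artifact). Aggregate = unweighted mean over qualifying
  bifurcations, on both vessel classes. Batch MAE ≈ 1.2° against truth.
- **VD (density).** Exact pixel fraction of the region.
- **VDf (fractal dimension).** Box counting with dyadic box sizes from
  2 px to a quarter of the frame, grid origin fixed at (0,0) for
  determinism (multi-offset averaging deliberately not used); VDf is the
  negative least-squares slope of log N(s) vs log s; fewer than three
  scales or fewer than two occupied boxes at the largest scale raise an
  error. Analytic patterns (line, filled square, Sierpinski triangle) are
  recovered within 0.05.
- **AVR.** Length-weighted mean artery caliber over length-weighted mean
  vein caliber; undefined when a class is missing.
- **Disc/cup.** Ellipse areas × pitch²; C/D is the area ratio; containment
  is checked.

## Peripapillary zones

One PD is the diameter of the circle with the disc ellipse's area. Annuli
at 0.5–1.0, 1.0–1.5, 1.5–2.0, 2.0–2.5 PD are measured from the disc
*border* (center distance minus the equal-area radius), half-open
inner-inclusive, hence pairwise disjoint. Quadrants split the plane along
the two 45° diagonals through the disc center (superior, nasal, inferior,
temporal; nasal/temporal swap with laterality) and are restricted to the
0.5–2.5 PD band, which they tile exactly — every band pixel belongs to
exactly one quadrant. The outermost annulus may be clipped by the frame;
metrics are then computed over the in-frame part.

## Cohort statistics

Both eyes enter as independent rows, as is common in such studies;
intra-subject correlation is acknowledged, not modeled (with the default
noise split the intraclass correlation is ≈ 0.09), and a subject-averaging
switch exists for sensitivity analysis. Baseline comparisons use pooled-
variance t-tests (Welch switchable) and Pearson chi-square without
continuity correction (Yates switchable). The group comparison is an
ANCOVA: `outcome ~ group + age + sex + axl` by least squares (statsmodels
OLS), sex coded male = 1, the group test being the extra-sum-of-squares F
between the covariate-only and full models, adjusted means evaluated at
the grand covariate means. Rank-deficient designs fail with the offending
column named. No multiple-testing correction is applied across parameters
and zones (a Holm option exists, off by default). Reports are emitted in
the conventional three-table layout: global parameters, annulus rows
labeled "0.5–1.0 PD" … "2.0–2.5 PD", and quadrant rows
Superior/Nasal/Inferior/Temporal.

## Reproducibility

Every stage is driven by explicit integer seeds; identical configuration
and seed reproduce bit-identical images, masks, covariate tables, and
metrics CSVs. A pipeline run writes a manifest (config hash, seed, package
versions) sufficient to re-run it exactly.

## Problem sizes used in the test suite

The default suite measures segmentation on one 1024² scene, metric
recovery on a 20-scene batch (~5,800 matched segments, ~1,300 matched
bifurcations), zone checks on four scenes, statistical operating
characteristics on 100 truth-level cohort replicates of 100 subjects per
group, and end-to-end determinism on a 2-subjects-per-group rendered run —
sizes at which every gate is stable across seeds.

## What the synthetic scenes do and do not show

The generator reproduces the *geometry* the measurements rely on
(tubular vessels with known widths, meanders, branch angles, a bright
disc/cup, PD-scaled zones) but not photographic realism: no choroidal or
nerve-fiber texture, no pathology (hemorrhages, drusen), no chromatic
aberration or capture artifacts, a simplified two-class intensity model
for arteries vs veins, and crossings resolved by a fixed layering rule.
Passing gates on these scenes therefore demonstrates that the estimators
are correct on well-posed vascular geometry at realistic sampling, not
that the classical segmenter matches a trained clinical model on real
photographs — which is why the segmenter sits behind a pluggable
interface and the truth-level cohort path exists for statistics.

## Known limitations

- Artery–vein crossings become degree-4 nodes; their incident segments are
  excluded from branch-angle metrics, and no crossing disambiguation is
  attempted.
- Caliber near the raster floor (≲ 2.5 px) is quantization-limited; the
  generator keeps vessels above ~1.8 px for this reason.
- The eye-level analysis understates standard errors in the presence of
  intra-subject correlation; the subject-mean mode is the conservative
  alternative.
- Quadrant fractal dimensions are computed on frame-clipped sectors and
  are grid-dependent at small region sizes.
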