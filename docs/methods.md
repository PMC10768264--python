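# Methods

## Measurement model

A lesion enters as a binary segmentation: either a 3D voxel mask with
per-axis spacing in mm (NIfTI, spacing from the header) or a 2D outline.
Voxel centres sit at `(index + 0.5) * spacing`; all lengths are mm, areas
mm², angles degrees.

**Maximal cross-section.** Every slice of the three orthogonal orientations
(axial, coronal, sagittal — no oblique planes) is scored by the in-plane
area of its largest connected foreground component (voxel count × pixel
area); the best slice wins, with ties resolved by plane precedence
axial > coronal > sagittal and then by lower slice index. The component is
contoured at the 0.5 iso-level of its Gaussian-smoothed indicator image
(σ = 1.5 voxels by default). Smoothing before contouring removes the
half-voxel staircase a raw binary marching-squares boundary carries; the
price is a curvature-dependent inward shift of order κσ²/2, below 2 µm for
lesions resolved by at least 4 voxels across the minor axis (the resolution
floor below which the generator warns). Components spanning a single voxel
row or column are rejected as degenerate rather than measured.

**Chords.** The contour is resampled to arc-length-uniform vertices
(clamped to [360, 2000]). LD is the exact maximum over all vertex pairs —
O(n²) is microseconds at this size and is its own oracle; ties resolve to
the lexicographically smallest index pair. PD is found by sweeping lines
exactly perpendicular to LD along the open segment AB at LD/500 per
station; at each station the polygon intersection is decomposed into inside
intervals and the interval straddling line AB is kept (so the crossing
point O exists), falling back to the longest interval for non-convex
shapes. Both the sweep resolution and the resampling bounds are exposed
parameters.

**Angle stability and the PD foot rule.** The vertex angles at A and B are
steep functions of where O divides AB (≈14°/mm for a 10 × 6 mm lesion), and
the width profile w(x) of a convex lesion is nearly flat around its
maximum. On voxel data the boundary carries correlated quantisation error
of ±5–10 µm even after smoothing, while w(x) varies by less than 10 µm over
±0.3 mm around its peak — so the raw sweep argmax wanders by a few tenths
of a millimetre, which barely changes PD but moves the angles by several
degrees. The mask pipeline therefore locates the foot with a composite
estimator (`foot_rule="auto"`): the mean of (a) the midpoint of the
contiguous near-maximal plateau (within 0.4% of the peak width) and (b) the
curvature-weighted vertex of parabolas fitted to w² over the two profile
wings, 0.05–0.25 LD away from the peak (for an elliptical arc, squared
half-width is exactly quadratic in the position along the axis, so the
wing fit localises the peak from data well outside the noisy flat top).
The two estimators respond to quantisation error with opposite signs and
their mean cancels most of it; when no concave wing fit exists (sharp,
tent-like profiles, e.g. a rectangle cut along its diagonal) the rule falls
back to the argmax, which is reliable precisely then. Measured on
rasterised bi-ellipses at 0.1 mm spacing over 15 rotations, worst-case
angle error is 1.8° and LD/PD errors stay below 0.3%; exact analytic
polygons keep the plain argmax (`foot_rule="argmax"`), which reproduces the
closed-form angles to <10⁻⁴ degrees. These errors scale roughly linearly
with voxel spacing.

**Angles.** angle_A is the angle between rays A→C and A→D (two-ray arccos
of normalised dot products), likewise angle_B; BiA/SmA are assigned by
magnitude, making the result invariant to relabelling A/B or C/D. Angles at
C and D are computed but enter no downstream statistic. PD ≤ LD holds by
construction (LD is the global longest chord), so LD/PD ≥ 1 and
BiA/SmA ≥ 1 are invariants, not assumptions.

## Synthetic nodules

The generator family is the bi-ellipse: half-ellipses with semi-major axes
a₁ ≥ a₂ glued on a shared minor semi-axis c ≤ a₂. Closed forms:

    LD = a1 + a2          PD = 2c           MA = pi c (a1 + a2) / 2
    angle at far endpoint  = 2 atan(c/a1)
    angle at near endpoint = 2 atan(c/a2)   BiA/SmA = atan(c/a2)/atan(c/a1)

Increasing a₁/a₂ at fixed c strictly increases BiA/SmA, reproducing the
asymmetry-to-angle-ratio link the descriptor is meant to capture. The
inverse map (LD, LD/PD, BiA/SmA) → (a₁, a₂, c) is one Brent root find on
a₂ ∈ [c, LD/2] and round-trips to 10⁻⁶. Volumes are built by extruding the
cross-section with the strictly peaked profile √(1 − |z|/H), H = 0.8c by
default: the apex slope is nonvanishing, so the central axial slice remains
the unique maximal cross-section even after pixel-count quantisation, and
H < c keeps coronal/sagittal sections smaller than the axial one.

**Cohorts.** The default `CohortSpec` encodes the study conditions: 39
preinvasive vs 59 invasive lesions; per-group (mean, SD) targets for LD,
LD/PD and BiA/SmA from the published comparison table; demographics (sex,
age, lobe) drawn from the published cohort composition. Draws are truncated
normals — LD to [3, 30] mm (the ≤3 cm inclusion criterion), ratios to
≥ 1.001. Two geometric couplings deserve note:

- A bi-ellipse cannot combine a near-circular LD/PD with a large BiA/SmA
  (the maximum feasible ratio is atan(1)/atan(c/(LD−c))). Independent
  draws from the published distributions violate this for ~20–28% of
  lesions, so the BiA/SmA draw is additionally truncated at the geometric
  maximum given the drawn LD/PD. The residual error guard (>10% of draws
  with an empty feasibility window) remains but does not fire under the
  defaults.
- The published invasive-group LD/PD of 1.491 ± 0.568 places ~19% of a
  normal below the geometric floor of 1; any ≥1-truncated normal with those
  parameters has mean ≈1.69. Sample means therefore match the targets
  within 2 SE for LD and BiA/SmA in both groups and for LD/PD in the
  preinvasive group, while the invasive LD/PD mean is structurally shifted
  upward by ≈0.2 — asserted as expected behaviour in the tests.

What the generator does *not* emulate: spiculation, lobulation and other
boundary irregularity of real GGNs (boundary jitter is available via
`noise_sd` but defaults to 0); attenuation/texture; solid cores; and any
within-group correlation between the three descriptors (they are drawn
independently, which is also why the combined two-feature AUC of the
clinical cohort is not a reproduction target). Passing tests show the
pipeline measures what the geometry defines, at the stated tolerances — not
that the descriptors behave identically on clinical boundaries.

## Statistics

- Pearson chi-square without continuity correction (scipy), df=(r−1)(c−1);
  this reproduces the published lobe-distribution p = 0.699. (The published
  sex p = 0.527 matches no standard chi-square variant; the exact Pearson
  statistic on that 2×2 table is 0.539, p = 0.463. Recorded, not chased.)
- Group comparisons report mean ± SD per group with both Welch's t-test and
  the two-sided Mann-Whitney U; Welch is the headline p-value. A feature
  constant in both groups yields NaN p-values with a flag, not an error.
- The logistic model is an unregularised maximum-likelihood fit
  (statsmodels Logit, Newton, tol 10⁻⁸, 100 iterations). Perfect
  separation is surfaced: the Newton failure is caught, the fit is retried
  with BFGS, and the results carry a `separation` flag plus a warning.
  Odds ratios are exp(coefficients) with Wald 95% intervals.
- ROC analysis uses the `score ≥ threshold → positive` convention over
  observed thresholds. The AUC is the Mann-Whitney U statistic (ties count
  ½), which equals the trapezoidal area under the empirical curve — both
  are computed and asserted equal to 10⁻¹² in tests. The 95% CI uses the
  DeLong placement-value variance by default, with a seeded percentile
  bootstrap (2000 resamples) as the alternative. The Youden cut-off is the
  observed score maximising sensitivity + specificity − 1, ties broken
  toward the smallest score, matching the "feature ≥ cut-off" phrasing of
  the published rule. No multiple-testing correction is applied anywhere,
  matching the original analysis.
- The published coefficient vector (−34.571, 28.443, 0.27) is a frozen
  `PublishedModel`; its P = 0.5 level set is the line
  28.443·x₁ + 0.27·x₂ = 34.571, and scoring a cohort with it is
  `combined_score_roc(cohort, model=PUBLISHED_MODEL)`.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| contour resampling | clamp to [360, 2000] vertices | chord search grid |
| PD sweep | 500 stations per LD | perpendicular-chord search |
| plateau tolerance | 0.4% of max width | foot rule, mask path |
| extraction smoothing | σ = 1.5 voxels | iso-contour of smoothed indicator |
| voxel spacing (generator) | 0.1 mm | ~60 voxels across a 6 mm lobe |
| cohort sizes | 39 / 59 | study group sizes |
| AUC simulation | 200 cohorts | acceptance-script replicate count |

The full test suite (geometry oracles, 1000-shape property sweeps, a
10 000-row logistic recovery, three rasterised-volume recoveries and the
200-cohort AUC simulations) runs in about one minute on one CPU; the
acceptance script takes a few seconds.

## Known limitations

- The angle descriptors are intrinsically ill-conditioned near symmetric
  shapes: when the width profile is flat, small boundary perturbations move
  O substantially. This affects manual measurement equally; the foot rule
  bounds but cannot eliminate it.
- Accuracy figures quoted here are for smooth convex-ish lesions ≥ 4 voxels
  across the minor axis; heavily spiculated boundaries will degrade the
  wing fits and fall back to the noisier plateau/argmax estimates.
- 2D mask input assumes the provided image *is* the maximal cross-section;
  no through-plane search is possible.
- The synthetic cohort inherits the independence caveat above: statistics
  that depend on descriptor correlation (notably the combined-model AUC)
  are internally consistent but not comparable to the clinical value.
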