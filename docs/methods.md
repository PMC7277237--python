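# Methods

## Problem and model

The package measures the long-axis angulation of mandibular molars
(FDI 36–38 left, 46–48 right) from per-tooth binary segmentation masks of
panoramic radiographs, and classifies third-molar eruption potential from
that angle. All geometry lives in one raster frame: x rightward, y
downward, 0-based indices, coordinates at pixel centers. A tooth angle is
measured from the image vertical and is positive when the occlusal end
points toward +x; clinically only the magnitude matters, and all
reporting (accuracy tables, eruption calls) uses magnitudes.

### Iterative contour regression

The estimator assumes that the mesial and distal surfaces of the crown
base and cervix run parallel to the tooth's long axis, while the occlusal
surface (cusps) and the root region (tapering, possibly bifurcated) do
not. Each iteration rotates the segmentation contour upright by the
current estimate, censors the non-informative ends, fits one
least-squares line per side wall, and corrects the estimate by the mean
residual inclination of the two lines. The fixed point of this map is the
angle at which the censored walls stand vertical.

Numerical and design choices:

- **Contour, not raster.** The contour is extracted once from the mask at
  sub-pixel resolution (marching squares at level 0.5) and rotated as
  coordinates; masks are never re-rasterized between iterations, so no
  resampling error accumulates.
- **Censor band** `[0.15, 0.55]` of the upright contour's vertical
  extent (top fraction removes the occlusal surface, bottom fraction the
  roots). Both fractions are configuration-exposed
  (`OrientationConfig`); a band that retains fewer than `min_band_rows`
  (8) distinct rows raises an error telling the caller to widen it.
- **Partial edge rows.** The band thresholds fall mid-row, so the first
  and last retained rows can contain points from one wall only; the
  per-row extremes rule would copy such a point into the opposite chain
  as a gross outlier. Edge rows whose x-spread is below half the median
  row spread are therefore dropped before splitting.
- **x-on-y ordinary least squares.** After the upright rotation the
  walls are near-vertical, so regressing x on y is well conditioned. A
  side line's `angle_deg` is `atan(dx/dy)`, positive when the line's
  bottom end points toward +x — opposite in sign to the tooth-angle
  convention. The update applied to the estimate is therefore the
  *negated* mean of the two line angles; with that orientation the map
  contracts (the literal sum diverges).
- **Equal weights.** The mesial and distal line angles are averaged
  unweighted even when their point counts differ.
- **Pivot.** The upright rotation pivots on the contour centroid; the
  resulting angle is pivot-invariant, the choice only keeps coordinates
  near the shape.
- **Ten iterations, no early stop** by default; on clean shapes the
  update magnitude is far below 0.1° at iteration 10. An optional
  `early_stop_tol_deg` terminates sooner. `converged` reports whether the
  last update fell below the tolerance (0.1° when early stopping is
  disabled). Masks under 200 foreground pixels trigger a warning, not an
  error.

### Landmark seed

The iteration needs a seed within its basin of attraction (empirically
tens of degrees wide). Clinically the seed comes from two reference
points — the occlusal-surface midpoint and the pulp-chamber floor — which
sit near the two ends of the long axis. The package estimates both from
mask geometry with a two-pass band heuristic: foreground centroids over
the 10–30% (upper crown) and 45–65% (cervix) bands of the occupied
vertical span give a first axis; the bands are then re-applied in the
frame rotated upright by that first estimate, where they cut clean
cross-sections, and the centroids are mapped back. The second pass
matters for strongly tilted teeth, where a horizontal band at the top of
the bounding box catches a crown corner instead of a cross-section; with
it, the seed stays within 5° of truth on clean phantoms across ±60°.
Externally supplied landmarks override the heuristic. The heuristic is a
geometric stand-in for a learned landmark detector, not a reconstruction
of one; its band fractions were chosen for the phantom family and are
module constants, not scientific claims.

### Eruption rule

A third molar is called *unfavorable* when its angle magnitude strictly
exceeds the critical angle (default 27.0°); exactly 27.0° is favorable,
since the underlying longitudinal finding concerns teeth *greater than*
the critical value. Calls within [24.5°, 29.5°] carry a `borderline`
flag regardless of verdict, reflecting the few degrees of projection
distortion inherent to panoramic imaging. Because the clinical reference
axis may be either the image vertical or the ipsilateral second molar's
axis, the CLI offers both an absolute mode and a relative mode (M3 angle
minus ipsilateral M2 angle); outputs are labelled with the mode.
Development stage uses the shortened Demirjian scale: A–D (no roots), E
(starting bifurcation), F–H (root length ≥ crown height); stage is user-
or generator-supplied metadata, never inferred from the image.

## Phantom generator

The phantom family replaces a private radiograph dataset; it generates
the features the estimator actually uses, at exactly known ground truth:

- a crown wider than the cervix, with a shallow two-cusp occlusal
  profile and its height of contour (maximum bulge) in the occlusal
  third, narrowing back to cervix width within the top 30% of the crown
  — below the bulge the proximal walls run parallel to the axis, as in
  real molars;
- near-vertical cervix walls;
- 0, 1 or 2 root prongs (0 encodes a rootless follicle, development
  stages A–D; 1 a starting bifurcation, stage E; 2 developed roots,
  stages F–H);
- a crown `asymmetry` parameter in [−0.3, 0.3] that skews the bulge
  widths mesially/distally;
- optional boundary noise: the outline is densified to ~2.5 px vertex
  spacing, then vertices receive i.i.d. Gaussian jitter and/or dropout;
  self-crossings introduced by noise are repaired by taking the largest
  valid polygon.

Default dimensions (px): crown 48 wide × 30 high, cervix 32 × 40, roots
30 long, tips 20 apart — proportions of a lower molar at a typical
panoramic pixel pitch, giving ~100 px tooth height.

Six-tooth scenes place M1–M3 of both sides along a shallow arch on a
320 × 1000 canvas. Per-position angle magnitudes are drawn from normal
distributions matching reported manual measurements on adolescent
orthodontic cohorts — M1 16.7° ± 5.2, M2 19.4° ± 6.8, M3 44.8° ± 11.2 —
truncated to [0°, 90°); the sign encodes the mesial tilt direction
(positive for right-side teeth, displayed image-left in standard
panoramic orientation, negative for left-side). Third-molar morphology is
sampled over the three shortened development-stage classes with
probabilities 117/174/209 out of 500, the stage distribution of a
500-tooth adolescent cohort; per-tooth dimensions are scaled ±10% with
crown asymmetry drawn uniform in [−0.1, 0.1]. All generators are
deterministic under a fixed seed.

### What the phantoms do and do not emulate

They emulate silhouette geometry: wider crown, parallel walls, censored
roots, known rotation, boundary noise. They do not emulate segmentation
*failures of a particular model* (under-segmented roots, merged
neighbors), overlapping adjacent anatomy (ramus, second-molar contact),
projection foreshortening, or realistic grey-level content — there are no
grey levels at all. Passing the recovery suite therefore shows that the
*measurement* stage is accurate and unbiased given a faithful silhouette;
it says nothing about how well any particular segmentation model produces
such silhouettes on real radiographs.

Rootless follicles are the hardest family member: without roots the
censor band sits higher on the shape, closer to the crown bulge, and
recovery errors there reach ~0.2° (vs ~0.1° RMSE elsewhere), with the
iteration occasionally ending in a sub-0.2° limit cycle rather than a
fixed point. This mirrors the clinical situation, where underdeveloped
third molars are the least constrained measurement targets.

## Validation statistics

- Pixel metrics: IoU = TP/(TP+FP+FN), precision = TP/(TP+FP), recall =
  TP/(TP+FN); undefined ratios (zero denominator) return NaN with a
  warning so batch evaluation continues. Hausdorff distance is computed
  between boundary pixel sets (4-connectivity boundary, image border
  counting as background) and is symmetric by default — the directed
  variant is exposed, since a one-line definition cannot distinguish the
  two; the symmetric form is the field's standard.
- Bland–Altman: differences oriented test − reference, sample (n−1)
  standard deviation, limits of agreement at bias ± 1.96 SD, inclusive
  bounds when counting coverage.
- ICC: two-way random effects, absolute agreement, single measurement
  (ICC(2,1)) with the F-based 95% CI, computed via pingouin. This is the
  standard inter-observer choice; the model tag is carried in the result
  so alternative conventions are never conflated silently.
- Error-interval accuracy at ±1°, ±2.5°, ±5° with inclusive bounds.

## Problem sizes

The test suite and the acceptance script use 200-phantom recovery
populations, 20-scene (120-tooth) end-to-end runs, 100 random mask pairs
(≤ 64×64 px) for metric-oracle checks, and n = 200–5000 simulated tables
for the agreement statistics — sizes at which Monte-Carlo error is well
below the asserted tolerances while a full run stays in the tens of
seconds.

## Known limitations

- The landmark heuristic assumes a mandibular molar-like silhouette
  (occlusal end up); maxillary teeth would need a flipped convention.
- Angles are only meaningful in [−90°, 90°]; a tooth rotated past
  horizontal is outside the model.
- The censor-band fractions assume roots comprise roughly the lower
  third of the tooth; extreme root lengths shift the band onto
  non-parallel anatomy (widen or narrow the band via `--band`).
- ICC confidence bounds inherit the backend's rounding (two decimals)
  and degenerate to the point estimate when the within-subject variance
  is exactly zero.
- Interactive refinement of segmentations or regression endpoints is out
  of scope; the library measures whatever mask it is given.
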