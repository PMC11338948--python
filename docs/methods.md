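# Methods

## Scope and model

`cxrtubes` implements the deterministic stage that sits *after* a
segmentation/classification network for tubes and lines on chest
radiographs. Its inputs are (i) per-class binary mask channels — "NGT
line", "CVC line", "CVC tip", "ETT tip" — (ii) anatomical landmark
coordinates, (iii) the 11 RANZCR-CLiP multilabel classifier scores, and
(iv) the pixel spacing in mm/pixel. Network training and inference, rib
detection, and vessel-anatomy criteria (the CVC 45° vessel-wall angle,
coil/kink and aberrant-vessel clauses) are out of scope; the rib-count
rulers in the criteria are used only through their centimetre surrogates
(two posterior ribs ≈ 3.5 cm, four ≈ 10 cm).

Coordinates are 0-based, origin top-left, y increasing downward, so
"above/cranial" means smaller y. Anisotropic spacing is supported; a
single configured value applies to both axes. Missing spacing is a hard
error — every rule threshold is metric — and a rule whose landmark is
absent returns *Indeterminate*, never a guess.

## The rule table

With `d` the signed mm of tip **above** the reference landmark
(`(landmark.y − tip.y) · spacing_row`):

| Tube | Normal | Borderline | Abnormal | Incompletely imaged |
|------|--------|------------|----------|---------------------|
| ETT (vs carina) | 35 ≤ d ≤ 70 | 0 < d < 35 or d > 70 | d ≤ 0, or at T1 level or above (when that landmark is given) | — |
| NGT (vs GE junction, arc length beyond) | ≥ 100 mm | 0 ≤ beyond < 100 mm | above the junction | off-film and < 100 mm visible |
| CVC (vs cavoatrial junction) | d ≥ 0 (Swan-Ganz always Normal) | −25 ≤ d < 0, or above the aortic arch (when given) | d < −25 | — |

Boundary values default to Normal (the criteria use strict "less
than"/"higher than" for Borderline); `boundary_inclusive_normal=False`
flips this. The −25 mm band approximating "the upper third of the right
atrium" has no landmark in the data model; 25 mm is an engineering
default, configurable via `ra_upper_third_mm`, and not derived from any
measurement. Rules compare the vertical (cranio-caudal) separation by
default because the criteria are phrased as above/below; straight-line
distance is always computed alongside for display, and
`distance_mode="euclidean"` switches the rules to it (sign carried over
from the vertical component).

## Score correction

For each tube the geometric category is compared with the classifier's
argmax label within the tube's group under the severity order
Normal < Borderline < Abnormal. When geometry is strictly worse, the
argmax label's score and the geometric category's label score are
**swapped**. The swap was chosen over additive or multiplicative
adjustments because it is deterministic, keeps the adjusted scores a
permutation of the originals within the group (so score calibration is
untouched), never downgrades, and is idempotent. Indeterminate and
Incompletely-Imaged assessments change nothing. Each rule has a stable
identifier (`ETT_LOW`, `ETT_HIGH`, `ETT_BELOW_CARINA`, `ETT_T1_HIGH`,
`NGT_SHORT`, `NGT_ABOVE_GEJ`, `NGT_INCOMPLETE`, `CVC_BELOW_CAJ`,
`CVC_BELOW_RA_THIRD`, `CVC_ABOVE_ARCH`, `SWAN_GANZ_NORMAL`); the
`enabled_rules` set reproduces the uncorrected system (empty set) or any
partial configuration.

The Swan-Ganz override suppresses all position rules, so by default it
only fires when the `SwanGanzPresent` score clears a deliberately high
threshold (0.9); callers who know the catheter type can pass the flag
explicitly to `assess_radiograph`.

## Tip extraction

Components use 8-connectivity (4-connectivity fragments thin diagonal
catheters), sorted by pixel count with bounding-box ties. The tip is the
component **centroid** (rounded for reporting, fractional kept
internally): tip masks are small blobs and the centroid is
rotation-stable. With several candidate tips, the one nearest the
reference landmark is assessed — when multiple CVCs are present, the one
closest to the cavoatrial junction is the one graded.

The NGT has no tip channel, so its tip is recovered from the line
skeleton: the endpoint farthest *by arc length* from the skeleton point
nearest the carina (the tube enters at the pharynx; its far end is the
tip). Endpoints on the image border are excluded whenever an interior
endpoint exists, because a border endpoint is where the tube enters or
leaves the film — without this exclusion a long visible entry segment can
out-distance the true tip. Without a carina the lowermost endpoint is
used. Every use of this gap-filling definition is logged.

## Skeleton arc length

Line length is measured on the skeleton (scikit-image skeletonization of
the largest component, computed on its bounding box) as the longest
endpoint-to-endpoint geodesic, resampled every 4 pixels with chord
lengths summed. Raw summation of unit/√2 pixel steps was rejected: it
overestimates oblique digital lines by up to ~8% (worst near 22.5°) and
double-counts spur branches, while the resampled geodesic reproduces
axis-aligned and diagonal lines exactly and stays within ~4% of the
analytic length for straight segments of 30–180 px at any angle and at
line thicknesses 1–3 (measured over 600 random segments). The
"beyond-the-GE-junction" distance is the graph geodesic from the skeleton
node nearest the junction to the tip node; its small positive bias is
covered by the generator's sampling margins (below).

## Evaluation

AUCs are one-vs-rest in the Mann–Whitney form (ties half). Confidence
intervals are percentile bootstrap (2.5/97.5) over **images**, 1000
resamples by default; resamples on which a metric is undefined are
redrawn (up to 10× the draw budget), and optional stratified resampling
within a label keeps rare classes from vanishing. Group-averaged AUCs
bootstrap the averaged statistic itself rather than averaging per-label
intervals (the alternative would understate the averaging's variance
reduction). Undefined AUCs (single-class labels) propagate as explicit
`"undefined"` report cells. Landmark error is per-image Euclidean
distance in mm, summarised as mean and SD — population SD (divide by n)
by default, switchable via `ddof` — and compared between conditions with
a two-sided paired t-test (identical inputs are guarded to p = 1).
A comparison is flagged significant only when p < 0.05 **and** the 95%
CIs do not overlap. No multiple-testing correction is applied.

## Sample size

The minimum cohort for detecting AUC `A1` against null `A0` uses the
Hanley–McNeil variance with `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`; achieved
power is `Φ((A1 − A0 − z_{1−α/2}√V0)/√V1)` with both variances evaluated
at the candidate group sizes. The negatives:positives ratio is fixed at
`(1−p)/p` (19 at p = 5%, rounded to the nearest integer otherwise) and
`n_pos` is incremented until the target power is reached; the incremental
search is cross-checked against an exhaustive scan in the tests. At
(A1 = 0.9, A0 = 0.7, α = 0.05 two-sided, power 0.8, p = 0.05) this gives
15 positives + 285 negatives = 300 cases.

## Synthetic data generator

The generator emulates the pipeline's *inputs*, not radiographs: no
pixel-level realism, no ECG-lead artifacts (the subgroup flag is sampled,
not rendered), no pathology. Defaults describe a 303-film ICU-like
cohort: ETT on 178/303 films (categories 140/33/5), CVC on 148/303
(98/27/12 + 11 Swan-Ganz), NGT on 39/303 (20/4/2/13 including
incompletely imaged), ECG leads on 151/303. Images are 640×640 px at
0.6 mm/px — a 38 cm field of view typical of a portable chest film, large
enough that a normally placed NGT (≥ 10 cm beyond the GE junction) fits.

Anatomy is drawn in plausible bands (carina centrally in the upper
chest; cavoatrial junction 25–45 mm below and 15–30 mm right of it; GE
junction in the lower third). Tube geometry is drawn *inversely* from the
rule table: the requested category fixes the admissible distance band and
the tip is sampled inside it with safety margins of a few mm (e.g. ETT
Normal at 37–68 mm instead of 35–70), sized so that tip-centroid
quantization (±0.5 px ≈ 0.3 mm) and arc-length error (a few %) cannot
flip the category; NGT Normal samples 115–135 mm beyond the junction
against the 100 mm threshold for the same reason. This closes the
generate → rasterize → extract → classify loop, which the tests require
to recover the requested category in ≥ 99% of films.

Scores follow a binormal model: the true label's latent value is
N(μ, 1) with μ = √2·Φ⁻¹(target AUC), competitors N(0, 1), both squashed
by a logistic — monotone, so the one-vs-rest AUC equals the target.
Reader noise is isotropic Gaussian displacement per landmark (default
3 mm per axis), clipped in-bounds. One global seed drives everything;
each image uses the substream keyed by (seed, index), so growing the
cohort never perturbs earlier images.

Because the generator's Borderline and Abnormal tips are *geometrically
detectable by construction*, enabling the rule correction raises the ETT
group AUC on synthetic cohorts. Passing that directional test shows the
machinery works end to end; it does not certify the size of the benefit
on real films, where segmentation errors, unusual anatomy and hardware
(pacemakers, ECG leads) degrade both masks and landmarks in ways the
generator does not model.

## Problem sizes used in tests

The default suite runs in about a minute on one CPU: oracle-equivalence
checks use 200–1000 random instances, the bootstrap-coverage check 200
replications × 1000 resamples at n = 500, the round trip 1000 synthetic
films, and the end-to-end determinism check a 40-film cohort with 50
bootstrap draws.

## Known limitations

* The "upper third of the right atrium" band and the synthetic anatomy
  bands are engineering choices, not measured anatomy.
* NGT "within the tracheobronchopulmonary system" cannot be detected
  geometrically here; it is reachable only through upstream NGT-Abnormal
  scores.
* CVC grading uses tip position only; catheters malpositioned at normal
  tip height (azygos placement, kinks, wrong vessel-wall angle) are not
  detected, which is why the correction helps ETT more than CVC.
* The score-swap model of "upgrading" is one of several defensible
  adjustment schemes; alternatives (e.g. setting the target score to the
  max) would change adjusted-score calibration but not the final labels.
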