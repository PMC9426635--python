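# Methods

## The measurement

The alpha angle (AA) is defined on an AP hip image by three geometric
objects: the circle of best fit over the femoral head, the mid-point of
the narrowest section of the femoral neck, and the point where the
head/neck outline leaves the circle. The package computes all three
from a single ordered landmark outline in which landmarks 15–30 trace
the femoral head from its inferior-medial to its superior-lateral
curvature, 8–12 and 32–36 flank the neck, and the remainder are
transitions. Coordinates are image units (x rightward, y downward)
converted to mm by `pixel_spacing_mm`; every decision threshold below
is stated in mm, so the conversion matters only when coordinates are
not already millimetric. Geometry assumes a left hip; right hips are
mirrored about the vertical image axis first, which preserves the
landmark traversal order relative to the anatomy.

### Circle of best fit

Algebraic least squares (Kåsa): minimise
`sum (x² + y² + ax + by + c)²` over landmarks 15–28, solved as a linear
system on mean-centred coordinates. For points sampled exactly on a
circle this is exact (and the circumcircle for three points); for
near-circular femoral heads the difference from geometric least squares
is orders of magnitude below the 1 mm decision threshold (the test
suite cross-checks against an iterative geometric fit). The fit stops
at landmark 28 — two landmarks short of the superior-lateral curvature
— precisely so that a cam bulge contributes as little as possible to
the circle it will later be measured against. `rms_error` of the fit is
reported for information; it takes no part in any decision.

### Narrowest neck

For every consecutive-pair segment of one neck chain, the clamped
segment-to-point distance to every landmark of the opposing chain is
evaluated, in both directions; the global minimum is the neck width and
the mid-point of the realising line is the neck point. Distances use
the line *segment* (perpendicular foot clamped to the endpoints), not
the infinite line: neck landmarks span a finite extent and the two
interpretations coincide exactly in the perpendicular-foot case. Ties
are broken by landmark order with exact floating-point comparison;
configurations with genuinely tied minima (exactly parallel walls) have
a non-unique mid-point, which is why the test fixtures for rigid
invariance use converging chains.

### Index point and the four model rules

The signed residual of a landmark is its distance to the circle centre
minus the radius. A per-image threshold T is drawn from the circle-fit
landmarks 15–28, and candidates c = 29…37 are scanned in increasing
landmark order (candidates whose required successors would pass
landmark 39 are skipped):

| model | threshold T | rule at candidate c |
|---|---|---|
| 1 | max signed residual, floored at 0 | r(c) > T and r(c+1) > r(c) |
| 2 | as model 1 | r(c) > T, r(c+1) > r(c), r(c+2) > r(c+1) |
| 3 | max **absolute** residual, floored at 1 mm | as model 2 |
| 4 | as model 3 | r(c) > T, r(c+1) > T, r(c+2) > T |

Model 1 is deliberately permissive and flags sub-visual deviations;
model 2 suppresses those at the cost of missing non-monotone bulges;
model 3's absolute residuals let an inside-lying fit inflate the
threshold, and its 1 mm floor encodes "discernible by eye"; model 4
(the default) drops the monotonicity requirement. All residual
comparisons are exact floating point — a residual of 0.96 mm does not
clear the 1 mm floor, and the rule-trace tests pin that behaviour.
When no candidate qualifies, the engine returns an explicit
`NO_DEVIATION` status with every intermediate populated rather than
inventing an angle; spherical femoral heads are a legitimate output
class, not an error.

### Intersection position and the angle

If the landmark preceding the index point lies inside the circle, the
segment between them crosses the circle and the exact crossing (the
root nearest the outside point; tangency, discriminant < 1e−12 r², is
treated as no crossing) is the intersection position. Otherwise models
1–2 approximate it by the preceding landmark and models 3–4 by
whichever of the landmarks before/on/after the index point has the
smallest absolute residual. The angle is the arccosine of the
normalised dot product between the centre→neck-midpoint and
centre→intersection vectors, in [0°, 180°]; cam is called at ≥ 60° by
default (the threshold is a parameter because 50/55/60/83° are all in
published use).

## Agreement statistics

Lin's CCC uses population (1/n) moments; its 95% CI applies the normal
approximation to the Fisher z-transform with Lin's asymptotic variance
and back-transforms. Cohen's kappa comes from the 2×2 cam table with
percentage agreement alongside; when both raters are constant, chance
agreement is 1 and kappa is returned as NaN rather than a fabricated
value. Mean absolute difference uses the sample SD (n−1). Bland–Altman
limits are mean ± 1.96 sample SD of the differences; pairs strictly
outside the limits are flagged by id. Pairs with a missing value in
either series are dropped listwise with the count logged.

## The synthetic generator

`SyntheticHipSpec` builds an outline in the head-centred neck frame: a
circular head of radius R (default 25 mm, cohort draws U(23.5, 27) mm,
bracketing adult femoral-head radii on AP images) sampled by landmarks
15–30 over a 270° arc starting and ending 45° from the neck axis, so
the inter-landmark spacing is 18°; neck chains built from a fixed shape
template scaled with R and the neck width (default 24 mm, cohort
U(22, 25) mm); i.i.d. Gaussian landmark noise (cohort default 0.3 mm,
matching sub-millimetre annotation accuracy). The narrowest-neck
construction is symmetric about the neck axis, so the measured neck
mid-point lies on the axis and angles from the axis are directly
comparable with measured alpha angles.

A cam is a raised-cosine radial bulge whose zero-slope onset edge sits
`cam_onset_deg` lateral of the neck axis and widens over
`cam_extent_deg` (default 40°) toward the neck, holding full amplitude
through the head-neck junction and fading out before the narrowest
neck stations — a cam deforms the junction, and letting it reach the
narrowest neck would drag the measured neck mid-point off-axis. By this
construction the onset angle *is* the ground-truth alpha angle; it is
`None` (not 0) when the amplitude is at or below the 1 mm residual
floor, mirroring the engine's `NO_DEVIATION` semantics. Cohort cams
draw onsets U(65, 100)° and amplitudes U(2, 6) mm.

Two deliberate stylisations, and what they imply about test evidence:

* The lateral outline terminates while still hugging the inside of the
  head circle, so a bulge-free outline *never* triggers the index-point
  rule. Real femoral necks eventually flare outside the head circle and
  real spherical-ish hips therefore receive small angles (~45°) at the
  head-neck junction rather than `NO_DEVIATION`; the generator trades
  that realism for a clean negative class. Passing tests show the
  decision rules and geometry are correct, not that real-cohort angle
  *distributions* are reproduced.
* Angular resolution is bounded by the landmark spacing: when no exact
  crossing exists the intersection snaps to a landmark, so measured
  angles cluster near landmark angles (≈63°, ≈81° for the default
  shape) and recovery accuracy is assessed against the one-spacing
  (18°) budget. Above ≈100° onset the circle fit itself absorbs the
  bulge (landmarks 27–28 sit inside it) and recovery saturates near the
  landmark-28 angle; recovery and monotonicity are therefore validated
  over the 65–100° range the cohort samples.

Because every *measured* synthetic angle exceeds 60°, the binary-rater
statistics in the simulated-rater harness are evaluated at a 70° cam
threshold, which splits the cohort's measured range so that both
classes occur; the engine's default remains 60°.

## Numerical choices

* Exact floating-point residual comparisons (no epsilon), as above.
* Tangency tolerance: discriminant < 1e−12 r² counts as no crossing.
* Circle fit solved via `lstsq` on centred coordinates; rank < 3
  (collinear landmarks) raises a degenerate-geometry error.
* Monotonicity of recovered angle vs onset is asserted with 0.5° slack:
  the circle fit shifts slightly as the bulge moves through the fit
  range, which can nudge plateau values by a few hundredths of a degree.
* All cohort randomness flows from one integer seed through
  `numpy.random.default_rng`; child seeds are drawn below 2³¹.

## Problem sizes

The validation batteries use 100 random neck configurations against a
10 000-point dense-sampling oracle, 400 hips for the crossing
invariant, a 200-hip cohort for parameter recovery, 50 hips × 3
transforms for invariance, 10 000 samples for Bland–Altman coverage,
and 50 noise draws per rater-noise level — sizes at which the
Monte-Carlo error of each check is far below its decision margin.

## Known limitations

* The candidate range for the index point (29–37) and the behaviour
  when no index point exists are engineering choices; upstream
  definitions leave both open.
* Only the cam deformity is modelled; pincer morphology, osteophytes
  and acetabular landmarks are out of scope, as is any image
  processing — the package consumes landmark files only.
* The CCC confidence interval is asymptotic (Fisher z); it degenerates
  to a point at |CCC| = 1 and is not trustworthy below n ≈ 10.
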