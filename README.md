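# hipalpha

Automated measurement of the **alpha angle (AA)** — the standard imaging
measure of cam morphology of the hip — from ordered landmark outlines of
the proximal femur on AP hip images (e.g. DXA scans), plus the agreement
statistics used to validate automatic against manual measurements, and a
synthetic outline generator with known ground truth.

Cam morphology is an aspherical bulging of the lateral femoral head that
is strongly associated with femoro-acetabular impingement and hip
osteoarthritis. The alpha angle quantifies it: with a circle of best fit
placed over the femoral head (centre *c*), the AA is the angle at *c*
between

* the line from *c* to the mid-point of the narrowest section of the
  femoral neck, and
* the line from *c* to the point where the head/neck outline first
  leaves the circle.

AA ≥ 60° is the conventional threshold for cam morphology (50°, 55° and
83° are also in published use; the threshold is a parameter here).

## Method

The input is a text file of ordered outline landmarks; landmarks 8–39
cover the femoral head and neck (1-based numbering, medial neck → head →
lateral neck). All geometry assumes a left hip; right-hip outlines are
mirrored first. The pipeline:

1. **Circle of best fit** to head landmarks 15–28 (algebraic
   least-squares; the range stops short of the superior-lateral
   curvature so a cam bulge does not inflate the fit).
2. **Residuals**: for each landmark, distance to the circle centre minus
   the radius (positive = outside the circle).
3. **Neck mid-point**: narrowest width between the medial (8–12) and
   lateral (32–36) neck chains by an exhaustive segment-to-point search;
   the mid-point of the narrowest line is the neck point.
4. **Index point**: first landmark after 28 judged truly outside the
   circle. Four model iterations of this rule are implemented; the
   final model (4) requires three consecutive residuals above a
   per-image threshold — the maximum absolute residual over landmarks
   15–28, floored at 1 mm. If no landmark qualifies the image is
   reported as `NO_DEVIATION` (no measurable departure from the circle).
5. **Intersection position**: exact segment–circle crossing when the
   landmark preceding the index point lies inside the circle, otherwise
   the neighbouring landmark closest to the circle.
6. **Alpha angle and cam classification** from the two lines above.

## Worked example

Simulate a cohort with known ground truth, measure it, and compare the
automatic measurements against a simulated manual rater (ground truth +
3° Gaussian rater noise, written to `demo/manual.csv`):

```sh
hipalpha simulate --n 100 --cam-fraction 0.33 --seed 7 --output demo/cohort
hipalpha compute  --input demo/cohort --output demo/auto.csv
hipalpha compare  --auto demo/auto.csv --manual demo/manual.csv \
                  --report demo/report.json --cam-threshold 70
```

prints

```
wrote 100 outlines + ground_truth.csv to demo/cohort
processed 100 images: 32 measured, 68 NO_DEVIATION, 0 errors; cam prevalence 31.0%
n = 32
CCC = 0.588 [0.417-0.719]
kappa = 0.385 [75.0% agreement]
mean absolute difference = 9.60 deg [SD 5.76]
Bland-Altman mean -9.45 deg, limits [-21.23, 2.33], 3 outliers
```

Reading the output: 32 of the 100 synthetic hips carry a cam bulge and
receive a measured angle; the 68 spherical heads never leave their
circle of best fit and are reported `NO_DEVIATION` rather than being
assigned an angle. The comparison then pairs the 32 measured angles
with the noisy "manual" ones: Lin's concordance correlation (CCC) with
its 95% CI, Cohen's kappa with percentage agreement for the binary cam
call (here at a 70° threshold, which splits this cohort's angle range),
the mean absolute difference, and Bland–Altman limits of agreement with
the ids of pairs falling outside them (`demo/report.json` holds the
same numbers as JSON).

The same pipeline as a library call:

```python
from hipalpha import SyntheticHipSpec, generate_outline, compute_alpha

outline, truth = generate_outline(
    SyntheticHipSpec(cam_onset_deg=80.0, cam_amplitude=3.0)
)
result = compute_alpha(outline, model_version=4)
print(truth, round(result.alpha_deg, 2), result.cam)   # 80.0 80.94 True
```

The measured 80.94° sits within one inter-landmark spacing (18°) of the
80° ground-truth onset — the resolution limit set by the outline's
landmark density.

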