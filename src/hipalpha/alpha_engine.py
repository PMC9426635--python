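"""Alpha-angle computation from outline landmarks.

The alpha angle (AA) quantifies cam morphology on an AP hip image: it is
the angle at the femoral-head centre between (i) the line to the
mid-point of the narrowest femoral neck and (ii) the line to the point
where the head/neck outline leaves the circle of best fit.  AA >= 60
degrees is the conventional definition of cam morphology.

Four model iterations of the index-point / intersection logic are
implemented.  All share the same circle fit (landmarks 15-28), residual
definition and neck mid-point; they differ in how the per-image residual
threshold is formed and how many consecutive supra-threshold landmarks
an index point needs:

model 1
    threshold = maximum signed residual over landmarks 15-28 (floored at
    0); index point = first landmark after 28 whose residual exceeds the
    threshold with the next landmark's residual larger still.
model 2
    as model 1, but three consecutive landmarks must leave the circle by
    strictly increasing residuals above the threshold.
model 3
    threshold becomes the maximum *absolute* residual over 15-28,
    floored at 1 mm; the approximated intersection position may move to
    the landmark before, on, or after the index point (smallest absolute
    residual); the increasing-triple rule of model 2 is retained.
model 4 (final)
    as model 3, but the three consecutive residuals need only stay above
    the threshold, not increase.

Residual comparisons are exact floating point: a residual of 0.96 mm
does not clear a 1 mm threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .geometry import (
    CircleFit,
    NeckMeasurement,
    ResidualProfile,
    compute_residuals,
    fit_circle,
    neck_narrowest,
    segment_circle_intersection,
)
from .points_io import OutlinePoints

__all__ = [
    "IndexPointResult",
    "IntersectionPosition",
    "AlphaAngleResult",
    "MODEL_VERSIONS",
    "CIRCLE_FIT_LANDMARKS",
    "RESIDUAL_LANDMARKS",
    "INDEX_CANDIDATES",
    "MIN_THRESHOLD_MM",
    "index_point_threshold",
    "find_index_point",
    "intersection_position",
    "alpha_angle",
    "classify_cam",
    "compute_alpha",
]

MODEL_VERSIONS = (1, 2, 3, 4)
#: Landmark range the head circle is fitted to (and thresholds drawn from).
CIRCLE_FIT_LANDMARKS = (15, 28)
#: Landmark range residuals are evaluated over.
RESIDUAL_LANDMARKS = (15, 39)
#: Index-point candidates: first landmark after the circle-fit range,
#: bounded so that two successors (<= 39) always exist.
INDEX_CANDIDATES = range(29, 38)
#: Minimum index-point threshold (models 3-4), the approximate limit of
#: what a deviation from the circle is discernible by eye on the image.
MIN_THRESHOLD_MM = 1.0


@dataclass(frozen=True)
class IndexPointResult:
    """Outcome of the index-point search for one image."""

    threshold_mm: float
    index_landmark: int | None
    status: str  # FOUND | NO_DEVIATION

    def __post_init__(self) -> None:
        if self.threshold_mm < 0:
            raise ValueError("threshold_mm must be >= 0")
        if self.status == "NO_DEVIATION" and self.index_landmark is not None:
            raise ValueError("NO_DEVIATION result cannot carry an index landmark")


@dataclass(frozen=True)
class IntersectionPosition:
    """Where the outline leaves the circle of best fit.

    ``EXACT_CROSSING`` coordinates lie on the fitted circle;
    ``APPROXIMATED`` coordinates coincide with an outline landmark.
    """

    coords: tuple[float, float]
    method: str  # EXACT_CROSSING | APPROXIMATED


@dataclass(frozen=True)
class AlphaAngleResult:
    """Full alpha-angle result for one image, with intermediates."""

    alpha_deg: float | None
    cam: bool | None
    model_version: int
    circle: CircleFit
    neck: NeckMeasurement
    index: IndexPointResult
    intersection: IntersectionPosition | None
    status: str  # OK | NO_DEVIATION
    source_id: str = ""


def _check_model(model_version: int) -> None:
    if model_version not in MODEL_VERSIONS:
        raise ValueError(f"model_version must be one of {MODEL_VERSIONS}")


def index_point_threshold(
    profile: ResidualProfile, model_version: int = 4
) -> float:
    """Per-image residual threshold from the circle-fit landmarks (15-28).

    Models 1-2 use the maximum signed residual (floored at 0: an
    all-inside fit must not yield a negative threshold).  Models 3-4 use
    the maximum absolute residual — landmarks inside the circle count as
    deviation too — floored at 1 mm so that near-perfect fits do not
    register sub-visual index points.
    """
    _check_model(model_version)
    first, last = CIRCLE_FIT_LANDMARKS
    values = [profile[k] for k in range(first, last + 1) if k in profile]
    if not values:
        raise ValueError("empty residual profile over the circle-fit landmarks")
    if model_version in (1, 2):
        return max(0.0, max(values))
    return max(MIN_THRESHOLD_MM, max(abs(v) for v in values))


def find_index_point(
    profile: ResidualProfile, threshold_mm: float, model_version: int = 4
) -> IndexPointResult:
    """First landmark after 28 judged to have truly left the circle.

    Candidates are scanned in increasing landmark order (clockwise along
    the outline).  The rule per model, with r() the signed residual and
    T the threshold:

    * model 1: ``r(c) > T`` and ``r(c+1) > r(c)``
    * models 2-3: ``r(c) > T``, ``r(c+1) > r(c)``, ``r(c+2) > r(c+1)``
    * model 4: ``r(c) > T``, ``r(c+1) > T``, ``r(c+2) > T``

    Candidates whose required successors are absent are skipped.  If no
    candidate qualifies the status is ``NO_DEVIATION``.
    """
    _check_model(model_version)
    n_successors = 1 if model_version == 1 else 2
    for c in INDEX_CANDIDATES:
        needed = range(c, c + n_successors + 1)
        if any(k not in profile for k in needed):
            continue
        r = [profile[k] for k in needed]
        if r[0] <= threshold_mm:
            continue
        if model_version == 1:
            ok = r[1] > r[0]
        elif model_version in (2, 3):
            ok = r[1] > r[0] and r[2] > r[1]
        else:
            ok = r[1] > threshold_mm and r[2] > threshold_mm
        if ok:
            return IndexPointResult(
                threshold_mm=threshold_mm, index_landmark=c, status="FOUND"
            )
    return IndexPointResult(
        threshold_mm=threshold_mm, index_landmark=None, status="NO_DEVIATION"
    )


def intersection_position(
    op: OutlinePoints,
    circle: CircleFit,
    profile: ResidualProfile,
    index: IndexPointResult,
    model_version: int = 4,
) -> IntersectionPosition:
    """Coordinates where the outline leaves the circle of best fit.

    If the landmark preceding the index point lies inside the circle
    (negative residual) the segment between the two crosses the circle
    and the exact crossing is used.  Otherwise (preceding landmark
    outside, or the segment tangent to the circle) there is no clear
    intersection and it is approximated by an outline landmark: models
    1-2 take the landmark before the index point; models 3-4 take
    whichever of the landmarks before / on / after the index point has
    the smallest absolute residual.
    """
    _check_model(model_version)
    if index.status != "FOUND" or index.index_landmark is None:
        raise ValueError("intersection_position requires a FOUND index point")
    c = index.index_landmark
    prev = c - 1
    if profile[prev] < 0.0:
        crossing = segment_circle_intersection(
            op.xy_mm(prev), op.xy_mm(c), circle
        )
        if crossing is not None:
            return IntersectionPosition(coords=crossing, method="EXACT_CROSSING")
    if model_version in (1, 2):
        chosen = prev
    else:
        candidates = [k for k in (prev, c, c + 1) if k in profile]
        chosen = min(candidates, key=lambda k: abs(profile[k]))
    x, y = op.xy_mm(chosen)
    return IntersectionPosition(coords=(float(x), float(y)), method="APPROXIMATED")


def alpha_angle(
    circle: CircleFit,
    neck: NeckMeasurement,
    intersection: IntersectionPosition,
) -> float:
    """Angle (degrees, in [0, 180]) between the neck-midpoint and
    intersection directions as seen from the head centre."""
    c = np.asarray(circle.centre, dtype=float)
    u = np.asarray(neck.midpoint, dtype=float) - c
    v = np.asarray(intersection.coords, dtype=float) - c
    nu = float(np.hypot(*u))
    nv = float(np.hypot(*v))
    if nu == 0.0 or nv == 0.0:
        raise geometry.DegenerateGeometryError(
            "alpha angle undefined: point coincides with the head centre"
        )
    cosang = float(u @ v) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def classify_cam(alpha_deg: float, cam_threshold_deg: float = 60.0) -> bool:
    """Cam morphology: alpha angle at or above the threshold (default 60)."""
    return alpha_deg >= cam_threshold_deg


def compute_alpha(
    op: OutlinePoints,
    model_version: int = 4,
    cam_threshold_deg: float = 60.0,
) -> AlphaAngleResult:
    """Run the full alpha-angle pipeline on one left-hip outline.

    circle fit (15-28) -> residuals (15-39) -> narrowest neck ->
    index-point threshold -> index-point search -> intersection position
    -> alpha angle -> cam classification.  When no landmark qualifies as
    an index point the result carries status ``NO_DEVIATION`` with all
    intermediates populated and no angle (the outline never measurably
    leaves the circle).
    """
    _check_model(model_version)
    if op.side != "left":
        raise ValueError(
            f"{op.source_id or 'outline'}: geometry assumes a left hip; "
            "mirror right-hip outlines first"
        )
    try:
        circle = fit_circle(op, *CIRCLE_FIT_LANDMARKS)
        profile = compute_residuals(op, circle, *RESIDUAL_LANDMARKS)
        neck = neck_narrowest(op)
        threshold = index_point_threshold(profile, model_version)
        index = find_index_point(profile, threshold, model_version)
        if index.status == "NO_DEVIATION":
            return AlphaAngleResult(
                alpha_deg=None,
                cam=None,
                model_version=model_version,
                circle=circle,
                neck=neck,
                index=index,
                intersection=None,
                status="NO_DEVIATION",
                source_id=op.source_id,
            )
        inter = intersection_position(op, circle, profile, index, model_version)
        alpha = alpha_angle(circle, neck, inter)
    except geometry.DegenerateGeometryError as exc:
        raise geometry.DegenerateGeometryError(
            f"{op.source_id or 'outline'}: {exc}"
        ) from exc
    return AlphaAngleResult(
        alpha_deg=alpha,
        cam=classify_cam(alpha, cam_threshold_deg),
        model_version=model_version,
        circle=circle,
        neck=neck,
        index=index,
        intersection=inter,
        status="OK",
        source_id=op.source_id,
    )
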