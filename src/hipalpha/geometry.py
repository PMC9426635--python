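"""Pure 2D geometric primitives for the alpha-angle pipeline.

All quantities are in millimetres.  The operations here are deliberately
free of any femur-specific policy: circle of best fit to a landmark
range, signed distance-to-circle residuals, the narrowest-width search
between two landmark chains, and segment/circle intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .points_io import LandmarkCoverageError, OutlinePoints

__all__ = [
    "CircleFit",
    "NeckMeasurement",
    "ResidualProfile",
    "DegenerateGeometryError",
    "fit_circle",
    "compute_residuals",
    "segment_point_distance",
    "neck_narrowest",
    "segment_circle_intersection",
]

#: Discriminant below this fraction of r^2 counts as tangency (no crossing).
TANGENCY_REL_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised for geometrically degenerate input (collinear points, ...)."""


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle: centre (mm), radius (mm) and RMS residual."""

    centre: tuple[float, float]
    radius: float
    rms_error: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise DegenerateGeometryError(f"non-positive radius {self.radius}")
        if self.rms_error < 0:
            raise ValueError("rms_error must be >= 0")


@dataclass(frozen=True)
class NeckMeasurement:
    """Narrowest femoral-neck line: its two endpoints, width and midpoint."""

    endpoint_a: tuple[float, float]
    endpoint_b: tuple[float, float]
    width: float
    midpoint: tuple[float, float]


@dataclass(frozen=True)
class ResidualProfile:
    """Signed distance-to-circle residual per landmark (positive = outside)."""

    residuals: Mapping[int, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "residuals", dict(self.residuals))

    def __getitem__(self, landmark: int) -> float:
        return self.residuals[landmark]

    def __contains__(self, landmark: int) -> bool:
        return landmark in self.residuals

    def landmarks(self) -> list[int]:
        return sorted(self.residuals)

    def subset(self, first: int, last: int) -> "ResidualProfile":
        return ResidualProfile(
            {k: v for k, v in self.residuals.items() if first <= k <= last}
        )


# -- circle of best fit --------------------------------------------------


def fit_circle(
    op: OutlinePoints, first_landmark: int = 15, last_landmark: int = 28
) -> CircleFit:
    """Fit a circle to a landmark range by algebraic least squares.

    Solves the Kasa linear system minimising
    ``sum_i (x_i^2 + y_i^2 + a x_i + b y_i + c)^2``; for points sampled
    exactly on a circle (and for exactly three points) this returns the
    true circle / circumcircle.  The default landmark range 15-28 covers
    the femoral head from its inferior-medial curvature while stopping
    short of the superior-lateral curvature, which avoids fitting the
    circle to a cam bulge.
    """
    if last_landmark - first_landmark + 1 < 3:
        raise LandmarkCoverageError("circle fit needs at least 3 landmarks")
    pts = op.landmarks_mm(range(first_landmark, last_landmark + 1))
    x, y = pts[:, 0], pts[:, 1]
    # centre the data for conditioning; the fit is translation-equivariant
    x0, y0 = x.mean(), y.mean()
    u, v = x - x0, y - y0
    A = np.column_stack([u, v, np.ones_like(u)])
    b = u * u + v * v
    sol, _res, rank, _sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise DegenerateGeometryError(
            f"{op.source_id or 'outline'}: collinear landmarks, circle fit degenerate"
        )
    cu, cv = sol[0] / 2.0, sol[1] / 2.0
    r_sq = sol[2] + cu * cu + cv * cv
    if r_sq <= 0:
        raise DegenerateGeometryError("circle fit collapsed to non-positive radius")
    radius = float(np.sqrt(r_sq))
    centre = (float(cu + x0), float(cv + y0))
    dists = np.hypot(x - centre[0], y - centre[1])
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)))
    return CircleFit(centre=centre, radius=radius, rms_error=rms)


def compute_residuals(
    op: OutlinePoints,
    circle: CircleFit,
    first_landmark: int = 15,
    last_landmark: int = 39,
) -> ResidualProfile:
    """Signed residual per landmark: distance to centre minus radius."""
    cx, cy = circle.centre
    residuals = {}
    for k in range(first_landmark, last_landmark + 1):
        x, y = op.xy_mm(k)
        residuals[k] = float(np.hypot(x - cx, y - cy) - circle.radius)
    return ResidualProfile(residuals)


# -- segment primitives --------------------------------------------------


def segment_point_distance(seg_start, seg_end, point):
    """Distance from ``point`` to the closest location *on* the segment.

    Returns ``(distance, closest_point)``.  The closest location is the
    perpendicular foot when it falls within the segment, otherwise the
    nearer endpoint.
    """
    a = np.asarray(seg_start, dtype=float)
    b = np.asarray(seg_end, dtype=float)
    p = np.asarray(point, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        raise DegenerateGeometryError("degenerate segment: endpoints coincide")
    t = float((p - a) @ ab) / denom
    t = min(1.0, max(0.0, t))
    closest = a + t * ab
    return float(np.hypot(*(p - closest))), (float(closest[0]), float(closest[1]))


MEDIAL_NECK_LANDMARKS = range(8, 13)
LATERAL_NECK_LANDMARKS = range(32, 37)


def neck_narrowest(op: OutlinePoints) -> NeckMeasurement:
    """Narrowest width of the femoral neck by the line-segment search.

    The medial neck is demarcated by landmarks 8-12 and the lateral neck
    by 32-36.  Every consecutive-pair segment on one side is tested
    against every point of the opposing side (in both directions); the
    globally shortest segment-to-point distance is the neck width, and
    the midpoint of the realising line is the femoral neck point.  Ties
    are broken by landmark order (first pair encountered wins); widths
    compare exactly.
    """
    medial = op.landmarks_mm(MEDIAL_NECK_LANDMARKS)
    lateral = op.landmarks_mm(LATERAL_NECK_LANDMARKS)

    best = None  # (width, point_on_segment, opposing_point)
    for chain, opposing in ((medial, lateral), (lateral, medial)):
        for i in range(len(chain) - 1):
            for q in opposing:
                d, closest = segment_point_distance(chain[i], chain[i + 1], q)
                if best is None or d < best[0]:
                    best = (d, closest, (float(q[0]), float(q[1])))
    assert best is not None
    width, pa, pb = best
    if width <= 0:
        raise DegenerateGeometryError("neck sides touch: zero narrowest width")
    mid = ((pa[0] + pb[0]) / 2.0, (pa[1] + pb[1]) / 2.0)
    return NeckMeasurement(endpoint_a=pa, endpoint_b=pb, width=width, midpoint=mid)


def segment_circle_intersection(p_inside, p_outside, circle: CircleFit):
    """Crossing of segment ``p_inside -> p_outside`` with a circle, or None.

    Solves the quadratic for the segment parametrised as
    ``p_inside + t (p_outside - p_inside)``, t in [0, 1].  Of the roots
    that fall on the segment, the one nearest ``p_outside`` is returned.
    A discriminant below ``1e-12 r^2`` (tangency) counts as no crossing.
    """
    a = np.asarray(p_inside, dtype=float)
    b = np.asarray(p_outside, dtype=float)
    c = np.asarray(circle.centre, dtype=float)
    d = b - a
    if float(d @ d) == 0.0:
        raise DegenerateGeometryError("coincident segment endpoints")
    f = a - c
    qa = float(d @ d)
    qb = 2.0 * float(f @ d)
    qc = float(f @ f) - circle.radius**2
    disc = qb * qb - 4.0 * qa * qc
    if disc < TANGENCY_REL_TOL * circle.radius**2:
        return None
    sq = float(np.sqrt(disc))
    roots = [(-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)]
    on_segment = [t for t in roots if 0.0 <= t <= 1.0]
    if not on_segment:
        return None
    t = max(on_segment)  # nearest p_outside
    pt = a + t * d
    return (float(pt[0]), float(pt[1]))
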