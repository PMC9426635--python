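"""Parametric proximal-femur outline generator with known ground truth.

Real outlines (and their manual annotations) come from restricted
cohort data, so the pipeline is exercised on synthetic hips instead.
The generator emits the landmark scheme the engine consumes — 39
ordered points of which 8-39 carry the femoral head and neck — built
from an explicit geometric model in the head-centred neck frame:

* a circular femoral head of radius R sampled by landmarks 15-30,
  equally spaced over a 270-degree arc from the inferior-medial
  curvature (landmark 15, 45 degrees medial of the neck axis) to the
  superior-lateral curvature (landmark 30, 45 degrees lateral);
* medial (8-12) and lateral (32-36) neck chains flanking a narrowest
  region of width ``neck_width`` centred on the neck axis, with
  landmarks 13-14 and 31 as transitions; the lateral chain hugs the
  inside of the head circle (all lateral points stay within ~0.5 mm of
  it) so that a spherical head never triggers the index-point rule and
  the engine reports NO_DEVIATION — the stylisation that makes "no cam"
  a well-defined negative class;
* an optional cam: a raised-cosine radial bulge of amplitude
  ``cam_amplitude`` whose zero-slope onset edge sits ``cam_onset_deg``
  lateral of the neck axis and which widens over ``cam_extent_deg``
  toward the neck, holding full amplitude through the head-neck
  junction and fading out before the narrowest neck stations (a cam
  deforms the junction, not the narrowest neck).  Because the
  narrowest-neck midpoint lies on the neck axis by construction, the
  onset angle *is* the ground-truth alpha angle;
* i.i.d. Gaussian landmark noise on both coordinates.

Landmarks 1-7 continue the medial neck distally so that written files
satisfy the 1-based numbering convention of the point-file dialects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .points_io import OutlinePoints

__all__ = ["SyntheticHipSpec", "generate_outline", "generate_cohort",
           "HEAD_ARC_SPAN_DEG", "INTER_LANDMARK_SPACING_DEG"]

#: Angular span of the head arc covered by landmarks 15-30.
HEAD_ARC_SPAN_DEG = 270.0
#: Angular spacing between adjacent head landmarks (= span / 15 gaps).
INTER_LANDMARK_SPACING_DEG = HEAD_ARC_SPAN_DEG / 15.0

# Lateral neck template (landmarks 31..39) at reference radius 25 mm:
# radial offsets from the narrowest-station radius, and half-width
# offsets from neck_width/2.  Scaled linearly with head_radius.
_REF_RADIUS = 25.0
_LAT_DRHO = np.array([0.79, 0.39, 0.09, 0.00, 0.04, 0.19, 0.44, 0.74, 1.09])
_LAT_DQ = np.array([3.3, 1.7, 0.7, 0.15, 0.0, 0.1, 0.35, 0.75, 1.3])
# Medial chain mirrors the distal part of the lateral template:
# landmarks 8..12 reuse template stations 8..4 (distal -> proximal).
_MED_STATIONS = [8, 7, 6, 5, 4]
# Medial transition 13-14 (angle from axis, radius/R) toward landmark 15.
_MED_TRANSITION = [(35.0, 0.978), (41.0, 0.990)]
# Distal medial padding, landmarks 1..7 as (axial, half-width) / reference.
_PAD_DQ = [
    (25.6, 19.6), (25.0, 18.4), (24.4, 17.3), (23.8, 16.3),
    (23.2, 15.4), (22.6, 14.6), (22.0, 13.9),
]

#: Bulges at or below this amplitude sit under the engine's 1 mm
#: residual floor and carry no ground-truth alpha angle.
DETECTION_FLOOR_MM = 1.0


@dataclass(frozen=True)
class SyntheticHipSpec:
    """Parameters of one synthetic hip outline.

    Lengths in mm, angles in degrees.  ``neck_axis_deg`` is the image
    direction from the head centre toward the neck.  ``cam_onset_deg``
    is the angle lateral of the neck axis at which the head outline
    starts leaving the circle — the ground-truth alpha angle.
    ``neck_length`` (head centre to narrowest neck station) defaults to
    the value that keeps the whole lateral chain just inside the head
    circle.
    """

    head_centre: tuple[float, float] = (60.0, 55.0)
    head_radius: float = 25.0
    neck_axis_deg: float = 60.0
    neck_width: float = 24.0
    neck_length: float | None = None
    cam_onset_deg: float | None = None
    cam_amplitude: float = 0.0
    cam_extent_deg: float = 40.0
    noise_sd: float = 0.0
    pixel_spacing_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_radius <= 0:
            raise ValueError("head_radius must be > 0")
        if not 0 < self.neck_width < 1.9 * self.head_radius:
            raise ValueError(
                "neck geometrically impossible: neck_width must be positive "
                "and smaller than the head chord"
            )
        if self.cam_onset_deg is not None and not 0 < self.cam_onset_deg < 180:
            raise ValueError("cam_onset_deg must lie in (0, 180)")
        if self.cam_amplitude < 0 or self.cam_extent_deg <= 0:
            raise ValueError("cam amplitude must be >= 0 and extent > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")
        if self.neck_length is not None and self.neck_length <= 0:
            raise ValueError("neck_length must be > 0")

    @property
    def narrowest_radius(self) -> float:
        """Distance from head centre to the narrowest lateral landmark."""
        h = self.neck_width / 2.0
        if self.neck_length is None:
            return 0.9645 * self.head_radius
        return float(np.hypot(self.neck_length, h))


def _bulge(psi_deg: np.ndarray, spec: SyntheticHipSpec) -> np.ndarray:
    """Radial cam bulge (mm) at lateral angles ``psi_deg`` from the axis."""
    if spec.cam_onset_deg is None or spec.cam_amplitude == 0.0:
        return np.zeros_like(psi_deg)
    delta = spec.cam_onset_deg - psi_deg
    out = np.zeros_like(psi_deg)
    ramp = (delta > 0) & (delta < spec.cam_extent_deg)
    out[ramp] = 0.5 * spec.cam_amplitude * (
        1.0 - np.cos(np.pi * delta[ramp] / spec.cam_extent_deg)
    )
    out[delta >= spec.cam_extent_deg] = spec.cam_amplitude
    return out


def generate_outline(
    spec: SyntheticHipSpec,
    source_id: str | None = None,
) -> tuple[OutlinePoints, float | None]:
    """Generate one outline and its ground-truth alpha angle.

    Returns ``(outline, ground_truth_alpha_deg)``; the truth is the cam
    onset angle when a bulge above the 1 mm detection floor is present,
    otherwise ``None`` (matching the engine's NO_DEVIATION semantics for
    spherical heads).  Deterministic given ``spec.seed``.
    """
    R = spec.head_radius
    scale = R / _REF_RADIUS
    h = spec.neck_width / 2.0
    rho_w = spec.narrowest_radius
    if rho_w <= h:
        raise ValueError(
            "neck geometrically impossible: narrowest station radius does "
            "not clear the half-width"
        )

    theta = np.radians(spec.neck_axis_deg)
    n_hat = np.array([np.cos(theta), np.sin(theta)])
    m_hat = np.array([-np.sin(theta), np.cos(theta)])  # medial perpendicular

    def at(phi_deg: float, rho: float) -> np.ndarray:
        """Point at angle phi from the neck axis (medial-first sense)."""
        phi = np.radians(phi_deg)
        return rho * (np.cos(phi) * n_hat + np.sin(phi) * m_hat)

    coords = np.zeros((39, 2))

    # landmarks 1-7: distal medial padding (axial, half-width frame)
    for i, (d, q) in enumerate(_PAD_DQ):
        coords[i] = d * scale * n_hat + q * scale * m_hat

    # lateral chain 31-39 from the template
    lat_rho = rho_w + _LAT_DRHO * scale
    lat_q = h + _LAT_DQ * scale
    if np.any(lat_q >= lat_rho):
        raise ValueError(
            "neck geometrically impossible: lateral half-width exceeds the "
            "chain radius"
        )
    lat_psi = np.degrees(np.arcsin(lat_q / lat_rho))
    for j in range(9):  # landmarks 31..39
        coords[30 + j] = at(360.0 - lat_psi[j], lat_rho[j])

    # medial chain 8-12 mirrors the distal lateral template
    for i, st in enumerate(_MED_STATIONS):  # landmarks 8..12
        rho = rho_w + _LAT_DRHO[st] * scale
        psi = np.degrees(np.arcsin((h + _LAT_DQ[st] * scale) / rho))
        coords[7 + i] = at(psi, rho)

    # medial transition 13-14
    for i, (phi, rho_rel) in enumerate(_MED_TRANSITION):
        coords[12 + i] = at(phi, rho_rel * R)

    # head arc 15-30
    phis = 45.0 + INTER_LANDMARK_SPACING_DEG * np.arange(16)
    for i, phi in enumerate(phis):
        coords[14 + i] = at(phi, R)

    # cam bulge: radial push on every point lateral of the axis, faded
    # out below landmark 32's angle so the bulge spares the narrowest
    # neck stations (which would drag the neck midpoint off-axis)
    axial = coords @ n_hat
    perp = coords @ m_hat
    psi_signed = np.degrees(np.arctan2(perp, axial))  # medial > 0
    lateral = psi_signed < 0
    psi_lat = -psi_signed[lateral]
    guard_lo = float(lat_psi.min()) - 0.5
    guard_hi = float(lat_psi[1])
    guard = np.clip((psi_lat - guard_lo) / (guard_hi - guard_lo), 0.0, 1.0)
    guard = 0.5 * (1.0 - np.cos(np.pi * guard))
    bulge = np.zeros(39)
    bulge[lateral] = _bulge(psi_lat, spec) * guard
    radii = np.hypot(coords[:, 0], coords[:, 1])
    with np.errstate(invalid="ignore"):
        coords += (bulge / np.where(radii == 0, 1.0, radii))[:, None] * coords

    coords += np.asarray(spec.head_centre, dtype=float)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, coords.shape)

    outline = OutlinePoints(
        points=coords / spec.pixel_spacing_mm,
        index_map={k + 1: k for k in range(39)},
        pixel_spacing_mm=spec.pixel_spacing_mm,
        side="left",
        source_id=source_id if source_id is not None else f"synthetic-{spec.seed}",
    )
    has_cam = (
        spec.cam_onset_deg is not None
        and spec.cam_amplitude > DETECTION_FLOOR_MM
    )
    truth = float(spec.cam_onset_deg) if has_cam else None
    return outline, truth


# -- cohorts -------------------------------------------------------------


def _default_sampler(rng: np.random.Generator, cam: bool) -> SyntheticHipSpec:
    """Draw one hip: mild anatomical variability, physiological cams.

    Head radii ~ U(23.5, 27) mm and neck widths ~ U(22, 25) mm bracket
    adult proximal-femur dimensions on AP images; cam onsets are drawn
    from U(65, 100) degrees — the range in which cam bulges present —
    with amplitudes U(2, 6) mm over a 40-degree extent.
    """
    return SyntheticHipSpec(
        head_centre=(60.0, 55.0),
        head_radius=float(rng.uniform(23.5, 27.0)),
        neck_axis_deg=float(rng.uniform(50.0, 70.0)),
        neck_width=float(rng.uniform(22.0, 25.0)),
        cam_onset_deg=float(rng.uniform(65.0, 100.0)) if cam else None,
        cam_amplitude=float(rng.uniform(2.0, 6.0)) if cam else 0.0,
        cam_extent_deg=40.0,
        noise_sd=0.3,
        seed=int(rng.integers(2**31)),
    )


def generate_cohort(
    n: int,
    cam_fraction: float = 0.33,
    seed: int = 0,
    spec_sampler: Callable[[np.random.Generator, bool], SyntheticHipSpec]
    | None = None,
) -> list[tuple[OutlinePoints, float | None]]:
    """Generate ``n`` hips with approximately ``cam_fraction`` cams.

    ``spec_sampler(rng, cam)`` may replace the default per-hip parameter
    draw.  Fully reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= cam_fraction <= 1.0:
        raise ValueError("cam_fraction must lie in [0, 1]")
    sampler = spec_sampler if spec_sampler is not None else _default_sampler
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        cam = bool(rng.random() < cam_fraction)
        spec = sampler(rng, cam)
        cohort.append(generate_outline(spec, source_id=f"sim{i:04d}"))
    return cohort
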