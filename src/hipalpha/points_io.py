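"""Reading and writing landmark point files and result tables.

Landmark files hold the ordered outline points of a proximal femur as
``x y`` coordinate pairs, one landmark per line (landmark numbers are
1-based: the first pair in the file is landmark 1).  Two dialects are
supported:

``simple_xy``
    one whitespace-separated ``x y`` pair per line; lines starting with
    ``#`` (and blank lines) are ignored.

``pts``
    the format used by several landmark-annotation tools: a ``version:``
    line, an ``n_points:`` line, and the coordinate pairs enclosed in
    braces.

Only landmarks 8-39 along the femoral head and neck take part in the
alpha-angle computation, so a file must resolve at least landmark 39.
All geometry downstream assumes a *left* hip; right-hip outlines are
mirrored with :func:`mirror_points` first.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "OutlinePoints",
    "PointsParseError",
    "LandmarkCoverageError",
    "REQUIRED_LANDMARKS",
    "read_points",
    "write_points",
    "mirror_points",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

#: Landmark numbers that must be present for alpha-angle computation.
REQUIRED_LANDMARKS = range(8, 40)


class PointsParseError(ValueError):
    """A landmark file could not be parsed."""


class LandmarkCoverageError(ValueError):
    """A required landmark number is absent from an outline."""


@dataclass(frozen=True)
class OutlinePoints:
    """Ordered outline landmarks of one proximal femur.

    Parameters
    ----------
    points
        ``(n, 2)`` array of raw coordinates in image units
        (x rightward, y downward).
    index_map
        Mapping from 1-based landmark number to row of ``points``.
    pixel_spacing_mm
        Millimetres per coordinate unit (> 0).  Defaults to 1.0, i.e.
        coordinates already in mm.
    side
        ``"left"`` or ``"right"``.  All geometry assumes left-hip
        orientation; mirror right hips first.
    source_id
        Opaque image identifier carried through to result tables.
    """

    points: np.ndarray
    index_map: Mapping[int, int]
    pixel_spacing_mm: float = 1.0
    side: str = "left"
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2); got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("outline coordinates must be finite")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "index_map", dict(self.index_map))
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be > 0")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        missing = [k for k in REQUIRED_LANDMARKS if k not in self.index_map]
        if missing:
            raise LandmarkCoverageError(
                f"{self.source_id or 'outline'}: missing landmarks "
                f"{missing[0]}..{missing[-1]} (8-39 are required)"
            )
        rows = list(self.index_map.values())
        if len(set(rows)) != len(rows):
            raise ValueError("index_map rows must be distinct")

    # -- accessors -------------------------------------------------------

    def xy(self, landmark: int) -> np.ndarray:
        """Raw (image-unit) coordinates of a 1-based landmark number."""
        try:
            return self.points[self.index_map[landmark]]
        except KeyError:
            raise LandmarkCoverageError(
                f"{self.source_id or 'outline'}: landmark {landmark} not present"
            ) from None

    def xy_mm(self, landmark: int) -> np.ndarray:
        """Coordinates of a landmark in millimetres."""
        return self.xy(landmark) * self.pixel_spacing_mm

    def landmarks_mm(self, landmarks: Iterable[int]) -> np.ndarray:
        """Stacked mm coordinates for several landmark numbers."""
        return np.array([self.xy_mm(k) for k in landmarks], dtype=float)

    @property
    def n_points(self) -> int:
        return len(self.points)


# -- landmark file I/O ---------------------------------------------------


def _parse_pair(token_line: str, path: Path, lineno: int) -> tuple[float, float]:
    tokens = token_line.split()
    if len(tokens) != 2:
        raise PointsParseError(
            f"{path}:{lineno}: expected 'x y' pair, got {token_line!r}"
        )
    try:
        return float(tokens[0]), float(tokens[1])
    except ValueError:
        raise PointsParseError(
            f"{path}:{lineno}: non-numeric coordinate in {token_line!r}"
        ) from None


def _read_simple_xy(path: Path) -> list[tuple[float, float]]:
    coords: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            coords.append(_parse_pair(stripped, path, lineno))
    return coords


def _read_pts(path: Path) -> list[tuple[float, float]]:
    coords: list[tuple[float, float]] = []
    n_declared: int | None = None
    in_body = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("version:"):
                continue
            if stripped.startswith("n_points:"):
                try:
                    n_declared = int(stripped.split(":", 1)[1])
                except ValueError:
                    raise PointsParseError(
                        f"{path}:{lineno}: bad n_points header {stripped!r}"
                    ) from None
                continue
            if stripped == "{":
                in_body = True
                continue
            if stripped == "}":
                in_body = False
                continue
            if not in_body:
                raise PointsParseError(
                    f"{path}:{lineno}: unexpected content outside braces: {stripped!r}"
                )
            coords.append(_parse_pair(stripped, path, lineno))
    if n_declared is not None and n_declared != len(coords):
        raise PointsParseError(
            f"{path}: header declares {n_declared} points but file has {len(coords)}"
        )
    return coords


def read_points(
    path,
    dialect: str = "simple_xy",
    pixel_spacing_mm: float = 1.0,
    side: str = "left",
    source_id: str | None = None,
) -> OutlinePoints:
    """Read a landmark file into an :class:`OutlinePoints`.

    The first coordinate pair in the file is landmark 1; numbering follows
    file order.  Landmarks 8-39 must all be present (at least 39 pairs).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "simple_xy":
        coords = _read_simple_xy(path)
    elif dialect == "pts":
        coords = _read_pts(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(coords) < 39:
        raise LandmarkCoverageError(
            f"{path}: only {len(coords)} points; landmarks up to 39 are required"
        )
    pts = np.asarray(coords, dtype=float)
    return OutlinePoints(
        points=pts,
        index_map={k + 1: k for k in range(len(pts))},
        pixel_spacing_mm=pixel_spacing_mm,
        side=side,
        source_id=source_id if source_id is not None else path.stem,
    )


def write_points(op: OutlinePoints, path, dialect: str = "simple_xy") -> None:
    """Write an outline back to disk; inverse of :func:`read_points`.

    Landmarks are written in landmark-number order starting at the lowest
    number present; ``read_points`` of the result recovers the coordinates
    exactly (``repr``-precision floats).
    """
    path = Path(path)
    order = sorted(op.index_map)
    if order != list(range(order[0], order[0] + len(order))) or order[0] != 1:
        raise ValueError(
            "write_points requires contiguous landmark numbering starting at 1"
        )
    rows = [
        (float(op.points[op.index_map[k]][0]), float(op.points[op.index_map[k]][1]))
        for k in order
    ]
    with open(path, "w") as fh:
        if dialect == "simple_xy":
            for x, y in rows:
                fh.write(f"{x!r} {y!r}\n")
        elif dialect == "pts":
            fh.write("version: 1\n")
            fh.write(f"n_points: {len(rows)}\n")
            fh.write("{\n")
            for x, y in rows:
                fh.write(f"{x!r} {y!r}\n")
            fh.write("}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def mirror_points(op: OutlinePoints, image_width: float) -> OutlinePoints:
    """Mirror a right-hip outline about the vertical image axis.

    ``x -> image_width - x`` for every point; the side flag becomes
    ``left``.  Landmark ordering is unchanged, so the outline traversal
    direction relative to the anatomy is preserved.  Applying the mirror
    to an already-left outline is a no-op apart from a warning.
    """
    if op.side == "left":
        warnings.warn(
            f"{op.source_id or 'outline'}: side is already 'left'; mirror skipped",
            stacklevel=2,
        )
        return op
    mirrored = op.points.copy()
    mirrored[:, 0] = image_width - mirrored[:, 0]
    return replace(op, points=mirrored, side="left")


# -- result tables -------------------------------------------------------

RESULT_COLUMNS = (
    "source_id",
    "alpha_angle_deg",
    "cam",
    "index_point_landmark",
    "status",
    "model_version",
)


def write_results(results: Sequence, path) -> None:
    """Write alpha-angle results as CSV, one row per image.

    Columns (fixed order): source_id, alpha_angle_deg, cam (0/1, blank if
    undetermined), index_point_landmark, status, model_version.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for res in results:
            alpha = res.alpha_deg
            cam = res.cam
            idx = res.index.index_landmark if res.index is not None else None
            writer.writerow(
                [
                    res.source_id,
                    "" if alpha is None else repr(float(alpha)),
                    "" if cam is None else int(cam),
                    "" if idx is None else idx,
                    res.status,
                    res.model_version,
                ]
            )


def read_results(path):
    """Read a results CSV written by :func:`write_results` into a DataFrame."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"source_id": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: result table missing columns {missing}")
    return df
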