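import numpy as np
import pytest

from hipalpha.points_io import OutlinePoints


def outline_from_coords(coords, pixel_spacing_mm=1.0, side="left",
                        source_id="test"):
    """OutlinePoints from an (n>=39, 2) array; landmark k = row k-1."""
    coords = np.asarray(coords, dtype=float)
    return OutlinePoints(
        points=coords,
        index_map={k + 1: k for k in range(len(coords))},
        pixel_spacing_mm=pixel_spacing_mm,
        side=side,
        source_id=source_id,
    )


def circle_outline(centre=(10.0, 20.0), radius=5.0, n=39):
    """All 39 landmarks on one circle (angles spread over a 300-deg arc)."""
    angles = np.radians(np.linspace(0.0, 300.0, n))
    pts = np.column_stack([
        centre[0] + radius * np.cos(angles),
        centre[1] + radius * np.sin(angles),
    ])
    return outline_from_coords(pts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
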