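"""Index-point rules, intersection logic and the alpha-angle computation.

The index-point battery encodes hand-traced outcomes of each model
rule on constructed residual profiles, including the early-spurious
pattern that separates model 1 from the stricter models and the
0.96 mm-below-floor miss that the 1 mm minimum threshold produces.
"""

import numpy as np
import pytest
from dataclasses import replace

from hipalpha.alpha_engine import (
    alpha_angle,
    classify_cam,
    compute_alpha,
    find_index_point,
    index_point_threshold,
    intersection_position,
    IndexPointResult,
)
from hipalpha.geometry import CircleFit, NeckMeasurement, ResidualProfile
from hipalpha.synthetic import (
    INTER_LANDMARK_SPACING_DEG,
    SyntheticHipSpec,
    generate_outline,
)

from conftest import outline_from_coords


def profile_1528(values):
    return ResidualProfile(dict(zip(range(15, 29), values)))


def profile_29(values, start=29):
    return ResidualProfile({start + i: v for i, v in enumerate(values)})


class TestIndexPointThreshold:
    def test_floor_active_for_small_residuals(self):
        prof = profile_1528(np.linspace(-0.2, 0.3, 14))
        assert index_point_threshold(prof, model_version=4) == 1.0

    def test_absolute_maximum_beats_floor(self):
        vals = np.linspace(-0.5, 2.5, 14)
        vals[0] = -3.1
        prof = profile_1528(vals)
        assert index_point_threshold(prof, model_version=4) == pytest.approx(3.1)
        assert index_point_threshold(prof, model_version=3) == pytest.approx(3.1)

    def test_signed_maximum_for_early_models(self):
        vals = np.linspace(-0.5, 2.5, 14)
        vals[0] = -3.1
        prof = profile_1528(vals)
        assert index_point_threshold(prof, model_version=1) == pytest.approx(2.5)

    def test_signed_maximum_floored_at_zero(self):
        prof = profile_1528(np.linspace(-2.0, -0.5, 14))
        assert index_point_threshold(prof, model_version=1) == 0.0

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            index_point_threshold(ResidualProfile({}), model_version=4)


# Hand-traced battery: (name, residuals for landmarks 29.., threshold,
# expected index landmark per model {1, 2, 3, 4}; None = NO_DEVIATION).
INDEX_BATTERY = [
    ("stated-example",
     [1.5, 1.2, 1.3, 0.4, 0.2, 0, 0, 0, 0, 0, 0], 1.0,
     {1: 30, 2: None, 3: None, 4: 29}),
    ("all-below-threshold",
     [0.0] * 11, 0.0, {1: None, 2: None, 3: None, 4: None}),
    ("monotone-ramp",
     [0.2, 0.5, 1.1, 1.4, 1.8, 2.2, 2.6, 3.0, 3.4, 3.8, 4.2], 1.0,
     {1: 31, 2: 31, 3: 31, 4: 31}),
    ("bump-0.96-under-1mm-floor",
     [0.3, 0.96, 0.9, 0.2, 0, 0, 0, 0, 0, 0, 0], 1.0,
     {1: None, 2: None, 3: None, 4: None}),
    ("same-bump-without-floor",
     [0.3, 0.96, 0.9, 0.6, 0.2, 0, 0, 0, 0, 0, 0], 0.5,
     {1: None, 2: None, 3: None, 4: 30}),
    ("early-spurious-vs-late-true-run",
     [0.2, 0.5, 1.1, 1.2, 0.9, 1.5, 2.0, 2.5, 3.0, 3.2, 3.4], 1.0,
     {1: 31, 2: 34, 3: 34, 4: 34}),
    ("non-monotone-plateau",
     [1.5, 1.4, 1.45, 1.6, 1.7, 0, 0, 0, 0, 0, 0], 1.0,
     {1: 30, 2: 30, 3: 30, 4: 29}),
    ("inside-dip-then-exit",
     [-0.5, -1.2, 0.3, 1.2, 1.5, 1.9, 2.4, 2.8, 3.0, 3.1, 3.2], 1.0,
     {1: 32, 2: 32, 3: 32, 4: 32}),
    ("run-at-end-needs-missing-successors",
     [0, 0, 0, 0, 0, 0, 0, 0, 2.0, 2.5], 1.0,
     {1: 37, 2: None, 3: None, 4: None}),
    ("exactly-at-threshold-never-qualifies",
     [1.0] * 11, 1.0, {1: None, 2: None, 3: None, 4: None}),
    ("flat-run-above-threshold",
     [2.0, 2.0, 2.0, 0, 0, 0, 0, 0, 0, 0, 0], 1.0,
     {1: None, 2: None, 3: None, 4: 29}),
    ("descending-run-above-threshold",
     [3.0, 1.5, 1.2, 0, 0, 0, 0, 0, 0, 0, 0], 1.0,
     {1: None, 2: None, 3: None, 4: 29}),
    ("late-window-all-models-agree",
     [0, 0, 0, 0, 0, 0.5, 1.2, 1.4, 1.7, 2.0, 2.4], 1.0,
     {1: 35, 2: 35, 3: 35, 4: 35}),
    ("zero-threshold-tiny-deviation",
     [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1], 0.0,
     {1: 29, 2: 29, 3: 29, 4: 29}),
]


class TestFindIndexPoint:
    @pytest.mark.parametrize("model", [1, 2, 3, 4])
    @pytest.mark.parametrize(
        "name,values,threshold,expected",
        INDEX_BATTERY,
        ids=[row[0] for row in INDEX_BATTERY],
    )
    def test_hand_traced_battery(self, name, values, threshold, expected, model):
        res = find_index_point(profile_29(values), threshold, model)
        if expected[model] is None:
            assert res.status == "NO_DEVIATION"
            assert res.index_landmark is None
        else:
            assert res.status == "FOUND"
            assert res.index_landmark == expected[model]

    def test_model4_finds_whenever_model2_does(self, rng):
        # model 2's strictly-increasing triple implies model 4's rule
        for _ in range(200):
            values = rng.normal(0.8, 1.0, 11)
            prof = profile_29(values)
            m2 = find_index_point(prof, 1.0, 2)
            m4 = find_index_point(prof, 1.0, 4)
            if m2.status == "FOUND":
                assert m4.status == "FOUND"
                assert m4.index_landmark <= m2.index_landmark


def _ray_outline(circle, residual_by_landmark):
    """Outline whose landmark k sits on a distinct ray at radius+residual."""
    coords = np.zeros((39, 2))
    cx, cy = circle.centre
    for k in range(39):
        angle = np.radians(5.0 + 8.0 * k)
        r = circle.radius + residual_by_landmark.get(k + 1, 0.0)
        coords[k] = (cx + r * np.cos(angle), cy + r * np.sin(angle))
    return outline_from_coords(coords)


class TestIntersectionPosition:
    CIRCLE = CircleFit(centre=(0.0, 0.0), radius=20.0, rms_error=0.0)

    def _setup(self, residuals):
        op = _ray_outline(self.CIRCLE, residuals)
        prof = ResidualProfile(residuals)
        return op, prof

    def test_sign_change_gives_exact_crossing(self):
        op, prof = self._setup({29: -0.5, 30: 2.0, 31: 2.5})
        idx = IndexPointResult(1.0, 30, "FOUND")
        inter = intersection_position(op, self.CIRCLE, prof, idx, 4)
        assert inter.method == "EXACT_CROSSING"
        assert np.hypot(*inter.coords) == pytest.approx(
            self.CIRCLE.radius, abs=1e-9 * self.CIRCLE.radius
        )

    def test_preceding_outside_model1_takes_preceding_point(self):
        op, prof = self._setup({29: 0.3, 30: 2.0, 31: 2.5})
        idx = IndexPointResult(1.0, 30, "FOUND")
        inter = intersection_position(op, self.CIRCLE, prof, idx, 1)
        assert inter.method == "APPROXIMATED"
        assert inter.coords == pytest.approx(tuple(op.xy_mm(29)))

    def test_model4_takes_smallest_absolute_residual_neighbour(self):
        op, prof = self._setup({29: 0.9, 30: 1.4, 31: 0.2})
        idx = IndexPointResult(0.8, 30, "FOUND")
        inter = intersection_position(op, self.CIRCLE, prof, idx, 4)
        assert inter.method == "APPROXIMATED"
        assert inter.coords == pytest.approx(tuple(op.xy_mm(31)))

    def test_no_deviation_input_raises(self):
        op, prof = self._setup({29: 0.0, 30: 0.0, 31: 0.0})
        idx = IndexPointResult(1.0, None, "NO_DEVIATION")
        with pytest.raises(ValueError):
            intersection_position(op, self.CIRCLE, prof, idx, 4)


class TestAlphaAngle:
    CIRCLE = CircleFit(centre=(0.0, 0.0), radius=20.0, rms_error=0.0)

    def _neck(self, midpoint):
        return NeckMeasurement(endpoint_a=(0, 0), endpoint_b=(0, 0),
                               width=1.0, midpoint=midpoint)

    def _inter(self, coords):
        from hipalpha.alpha_engine import IntersectionPosition
        return IntersectionPosition(coords=coords, method="APPROXIMATED")

    def test_orthogonal_is_90(self):
        a = alpha_angle(self.CIRCLE, self._neck((0.0, -20.0)),
                        self._inter((10.0, 0.0)))
        assert a == pytest.approx(90.0)

    def test_diametrically_opposite_is_180(self):
        a = alpha_angle(self.CIRCLE, self._neck((0.0, -20.0)),
                        self._inter((0.0, 20.0)))
        assert a == pytest.approx(180.0)

    def test_constructed_60_degree_rotation(self):
        # rotate the neck direction by 60 degrees about the centre
        neck_dir = np.array([0.0, -1.0])
        th = np.radians(60.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        inter = tuple(20.0 * (R @ neck_dir))
        a = alpha_angle(self.CIRCLE, self._neck((0.0, -20.0)),
                        self._inter(inter))
        assert a == pytest.approx(60.0)

    def test_centre_coincident_raises(self):
        from hipalpha.geometry import DegenerateGeometryError
        with pytest.raises(DegenerateGeometryError):
            alpha_angle(self.CIRCLE, self._neck((0.0, 0.0)),
                        self._inter((10.0, 0.0)))


class TestClassifyCam:
    @pytest.mark.parametrize("alpha,expected",
                             [(60.0, True), (59.999, False), (106.2, True)])
    def test_inclusive_60_threshold(self, alpha, expected):
        assert classify_cam(alpha) is expected

    def test_custom_threshold(self):
        assert classify_cam(56.0, cam_threshold_deg=55.0) is True


class TestComputeAlpha:
    def test_spherical_head_no_deviation(self):
        op, truth = generate_outline(SyntheticHipSpec())
        res = compute_alpha(op)
        assert truth is None
        assert res.status == "NO_DEVIATION"
        assert res.alpha_deg is None and res.cam is None
        assert res.circle.radius == pytest.approx(25.0, rel=1e-6)

    def test_cam_recovered_within_one_landmark_spacing(self):
        op, truth = generate_outline(
            SyntheticHipSpec(cam_onset_deg=75.0, cam_amplitude=3.0)
        )
        res = compute_alpha(op)
        assert res.status == "OK"
        assert abs(res.alpha_deg - truth) <= INTER_LANDMARK_SPACING_DEG
        assert res.cam is True

    def test_unit_invariance(self):
        op, _ = generate_outline(
            SyntheticHipSpec(cam_onset_deg=80.0, cam_amplitude=3.0,
                             noise_sd=0.2, seed=3)
        )
        base = compute_alpha(op).alpha_deg
        scaled = replace(op, points=op.points * 2.0,
                         pixel_spacing_mm=op.pixel_spacing_mm / 2.0)
        assert compute_alpha(scaled).alpha_deg == pytest.approx(base, abs=1e-9)

    def test_right_hip_rejected_until_mirrored(self):
        op, _ = generate_outline(SyntheticHipSpec(cam_onset_deg=80.0,
                                                  cam_amplitude=3.0))
        right = replace(op, side="right")
        with pytest.raises(ValueError, match="left"):
            compute_alpha(right)

    def test_found_index_has_three_residuals_above_floor(self):
        from hipalpha.alpha_engine import compute_alpha as ca
        from hipalpha.geometry import compute_residuals, fit_circle

        op, _ = generate_outline(
            SyntheticHipSpec(cam_onset_deg=85.0, cam_amplitude=4.0,
                             noise_sd=0.3, seed=11)
        )
        res = ca(op, model_version=4)
        assert res.status == "OK"
        prof = compute_residuals(op, res.circle, 15, 39)
        c = res.index.index_landmark
        assert all(prof[k] > 1.0 for k in (c, c + 1, c + 2))
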