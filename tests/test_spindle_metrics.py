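import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleavekit.errors import AmbiguousSideError, GeometryError, InvalidPoseError
from cleavekit.geometry2d import Contour, polygon_centroid, rotate
from cleavekit.spindle_metrics import (
    AxisFrame,
    SpindlePose,
    centering_ratio,
    division_prediction,
    spindle_angle,
)

from .oracles import circular_segment_area, raycast_edge_distances


def pose_at_angle(center, angle_deg, length=0.6, plate_shift=0.0):
    """Pose tilted by angle_deg from +y, vegetal pole displaced toward +x."""
    u = rotate(np.array([0.0, 1.0]), angle_deg)  # vegetal -> animal
    center = np.asarray(center, float)
    plate = center + plate_shift * u
    return SpindlePose(pole_animal=plate + 0.5 * length * u,
                       pole_vegetal=plate - 0.5 * length * u,
                       plate=plate)


class TestPoseInvariants:
    def test_coincident_poles_rejected(self):
        with pytest.raises(InvalidPoseError):
            SpindlePose((1, 1), (1, 1))

    def test_plate_off_axis_rejected(self):
        with pytest.raises(InvalidPoseError):
            SpindlePose((0, 1), (0, 0), plate=(0.3, 0.5))

    def test_plate_defaults_to_midpoint(self):
        pose = SpindlePose((0, 1), (0, 0))
        assert pose.plate == pytest.approx([0, 0.5])


class TestSpindleAngle:
    def test_aligned_pose_is_zero(self, frame_up):
        assert spindle_angle(pose_at_angle((0, 0), 0.0), frame_up) == 0.0

    def test_45_toward_sign_reference_is_positive(self, frame_up):
        # vegetal pole displaced toward +x => +45
        assert spindle_angle(pose_at_angle((0, 0), 45.0),
                             frame_up) == pytest.approx(45.0)
        assert spindle_angle(pose_at_angle((0, 0), -45.0),
                             frame_up) == pytest.approx(-45.0)

    def test_perpendicular_reports_plus_90(self, frame_up):
        assert spindle_angle(pose_at_angle((0, 0), 90.0), frame_up) == 90.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(angle=st.floats(-89.9, 89.9), frame_rot=st.floats(0, 360))
    def test_matches_direct_atan2_construction(self, angle, frame_rot):
        """Signed angle equals the direct atan2 of the two directions."""
        av = rotate(np.array([0.0, 1.0]), frame_rot)
        frame = AxisFrame((0, 0), av, rotate(av, -90.0))
        u = rotate(av, angle)  # rotating toward -90-side = toward sign_ref
        pose = SpindlePose(pole_animal=u, pole_vegetal=-u)
        # brute force: atan2 between the apolar spindle line and av
        raw = float(np.degrees(np.arctan2(av[0] * u[1] - av[1] * u[0],
                                          np.dot(av, u))))
        expected = ((raw + 90.0) % 180.0) - 90.0  # fold to (-90, 90]
        if expected == -90.0:
            expected = 90.0
        assert spindle_angle(pose, frame) == pytest.approx(expected, abs=1e-9)

    def test_antisymmetric_under_reflection(self, frame_up):
        pose = pose_at_angle((0.3, 0.2), 27.0)
        mirrored = SpindlePose(
            pole_animal=pose.pole_animal * [-1, 1] + [0.6, 0],
            pole_vegetal=pose.pole_vegetal * [-1, 1] + [0.6, 0],
        )
        assert spindle_angle(mirrored, frame_up) == pytest.approx(
            -spindle_angle(pose, frame_up))


class TestCenteringRatio:
    def test_centered_plate_is_half(self, unit_square):
        res = centering_ratio(unit_square, pose_at_angle((0.5, 0.5), 0.0))
        assert res.value == pytest.approx(0.5)
        assert res.d_animal == pytest.approx(0.5)

    def test_vegetal_shifted_plate(self, unit_square):
        pose = SpindlePose((0.5, 0.45), (0.5, 0.05), plate=(0.5, 0.25))
        res = centering_ratio(unit_square, pose)
        assert res.d_animal == pytest.approx(0.75)
        assert res.d_vegetal == pytest.approx(0.25)
        assert res.value == pytest.approx(0.75)

    def test_mirror_complement_sums_to_one(self, unit_square):
        a = centering_ratio(unit_square,
                            pose_at_angle((0.5, 0.5), 0.0, plate_shift=-0.2))
        b = centering_ratio(unit_square,
                            pose_at_angle((0.5, 0.5), 0.0, plate_shift=+0.2))
        assert a.value + b.value == pytest.approx(1.0)

    def test_matches_boundary_raycast_oracle(self, rng):
        poly = Contour(np.array([(2.2, 0), (1.1, 1.9), (-1, 1.6), (-2.3, 0.1),
                                 (-0.9, -2.0), (1.4, -1.7)]))
        plate = np.array([0.2, -0.3])
        direction = np.array([0.4, 1.0]) / np.hypot(0.4, 1.0)
        pose = SpindlePose(plate + direction, plate - direction, plate=plate)
        res = centering_ratio(poly, pose)
        d_fwd, d_back = raycast_edge_distances(poly, plate, direction,
                                               n_samples=400000)
        assert res.d_animal == pytest.approx(d_fwd, abs=1e-3)
        assert res.d_vegetal == pytest.approx(d_back, abs=1e-3)

    def test_error_names_the_missing_side(self):
        tri = Contour([(0, 0), (2, 0), (1, 2)])
        pose = SpindlePose((1, 3.0), (1, 2.5))  # entirely above the apex
        with pytest.raises(GeometryError):
            centering_ratio(tri, pose)


class TestDivisionPrediction:
    def test_circle_center_halves_for_any_direction(self, circle720):
        for angle in (0.0, 17.0, 63.0, 90.0):
            pred = division_prediction(circle720,
                                       pose_at_angle((0, 0), angle, length=5))
            assert pred.relative_animal == pytest.approx(0.5, abs=1e-4)

    def test_unit_square_off_center_plate(self, unit_square):
        pose = SpindlePose((0.5, 0.9), (0.5, 0.1), plate=(0.5, 0.6))
        pred = division_prediction(unit_square, pose)
        assert pred.relative_animal == pytest.approx(0.4)
        assert pred.area_animal + pred.area_vegetal == pytest.approx(1.0)

    def test_half_disc_cut_at_centroid_closed_form(self):
        """Horizontal cut of the upper half-disc at its centroid height."""
        # flat edge on y=0, arc above: rotate the canonical half-disc by +90
        from cleavekit.shape_models import ShapeSpec, make_shape
        hd = make_shape(ShapeSpec("half_disc", radius=1.0, n_vertices=720,
                                  orientation_deg=90.0))
        c = polygon_centroid(hd)
        assert c == pytest.approx([0, 4 / (3 * np.pi)], abs=1e-3)
        pose = pose_at_angle(c, 0.0, length=0.6)
        pred = division_prediction(hd, pose)
        expected = circular_segment_area(4 / (3 * np.pi)) / (np.pi / 2)
        assert expected == pytest.approx(0.476, abs=0.005)
        assert pred.relative_animal == pytest.approx(expected, abs=0.005)

    def test_ambiguous_side_raises(self, unit_square):
        # animal pole exactly on the cleavage line through the plate
        pose = SpindlePose((0.5, 0.5), (0.5, 0.1), plate=(0.5, 0.5))
        with pytest.raises(AmbiguousSideError):
            division_prediction(unit_square, pose)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(rot=st.floats(0, 360), tx=st.floats(-30, 30), ty=st.floats(-30, 30))
    def test_rigid_invariance(self, rot, tx, ty):
        vertices = np.array([(2.5, 0), (1, 2), (-1.5, 1.8), (-2, -0.5), (0.5, -2)])
        contour = Contour(vertices)
        pose = pose_at_angle((0.2, 0.1), 20.0, plate_shift=0.15)
        base = division_prediction(contour, pose).relative_animal
        shift = np.array([tx, ty])
        moved = Contour(np.array([rotate(v, rot) for v in vertices]) + shift)
        moved_pose = SpindlePose(
            pole_animal=rotate(pose.pole_animal, rot) + shift,
            pole_vegetal=rotate(pose.pole_vegetal, rot) + shift,
            plate=rotate(pose.plate, rot) + shift,
        )
        assert division_prediction(moved, moved_pose).relative_animal == \
            pytest.approx(base, abs=1e-9)
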