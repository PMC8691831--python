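import numpy as np
import pytest

from cleavekit.geometry2d import Contour, Line2, polygon_centroid
from cleavekit.shape_models import ShapeSpec, make_shape
from cleavekit.spindle_metrics import line_contour_intersections
from cleavekit.virtual_experiments import (
    apply_tilt_centered,
    chord_pivot_sweep,
    reposition_centered,
    tilt_experiment,
)

from .oracles import mc_split_fraction


class TestRepositionCentered:
    def test_unit_square(self, unit_square, frame_up):
        pose = reposition_centered(unit_square, frame_up)
        assert pose.plate == pytest.approx([0.5, 0.5])
        assert pose.direction == pytest.approx([0, 1])
        # poles at 0.8 of the chord, symmetric about the plate
        assert pose.pole_animal == pytest.approx([0.5, 0.9])
        assert pose.pole_vegetal == pytest.approx([0.5, 0.1])

    def test_av_symmetric_lens_plate_on_axis(self, frame_up):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        lens = Contour(np.column_stack([np.cos(t), 2.5 * np.sin(t)]),
                       axis_frame=frame_up)
        pose = reposition_centered(lens, frame_up)
        assert abs(pose.plate[0]) < 1e-9

    def test_plate_equidistant_from_chord_ends(self, rng, frame_up):
        from .oracles import random_star_polygon
        hull_pts = random_star_polygon(rng, n_min=10, n_max=14)
        import scipy.spatial
        hull = scipy.spatial.ConvexHull(hull_pts)
        contour = Contour(hull_pts[hull.vertices])
        pose = reposition_centered(contour, frame_up)
        line = Line2(pose.plate, frame_up.av_direction)
        ts = [line.coordinate(p)
              for p in line_contour_intersections(contour, line)]
        assert max(ts) == pytest.approx(-min(ts), abs=1e-9)


class TestApplyTiltCentered:
    def test_zero_tilt_is_identity(self, unit_square, frame_up):
        pose = reposition_centered(unit_square, frame_up)
        tilted = apply_tilt_centered(unit_square, pose, 0.0, frame=frame_up)
        assert tilted.plate == pytest.approx(pose.plate)
        assert tilted.direction == pytest.approx(pose.direction)

    @pytest.mark.parametrize("tilt", [5.0, 20.0, -35.0, 60.0])
    def test_square_plate_stays_at_center(self, unit_square, frame_up, tilt):
        # central symmetry: every chord through the centre is centred there
        pose = reposition_centered(unit_square, frame_up)
        tilted = apply_tilt_centered(unit_square, pose, tilt, frame=frame_up)
        assert tilted.plate == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_tilt_angle_is_applied(self, half_disc, frame_up):
        pose = reposition_centered(half_disc, frame_up)
        for tilt in (10.0, -25.0):
            tilted = apply_tilt_centered(half_disc, pose, tilt, frame=frame_up)
            dot = float(np.dot(tilted.direction, pose.direction))
            assert np.degrees(np.arccos(np.clip(dot, -1, 1))) == \
                pytest.approx(abs(tilt), abs=1e-6)

    def test_half_disc_plate_is_self_consistent_chord_midpoint(self, half_disc,
                                                               frame_up):
        pose = reposition_centered(half_disc, frame_up)
        tilted = apply_tilt_centered(half_disc, pose, 10.0, frame=frame_up)
        line = Line2(tilted.plate, tilted.direction)
        ts = [line.coordinate(p)
              for p in line_contour_intersections(half_disc, line)]
        assert max(ts) == pytest.approx(-min(ts), abs=1e-8)
        # independent closed form: with both chord ends on the arc, the
        # chord midpoint is the projection of the disc centre (origin)
        # onto the tilted line through the starting plate
        d = tilted.direction
        expected = pose.plate - float(np.dot(pose.plate, d)) * d
        assert tilted.plate == pytest.approx(expected, abs=1e-4)


class TestTiltExperiment:
    def test_symmetric_contour_zero_tilt_is_equal(self, frame_up):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        lens = Contour(np.column_stack([np.cos(t), 2.0 * np.sin(t)]))
        res = tilt_experiment(lens, frame_up, 0.0)
        assert res.prediction_untilted.relative_animal == \
            pytest.approx(0.5, abs=1e-6)
        assert res.prediction_tilted.relative_animal == \
            pytest.approx(0.5, abs=1e-6)

    def test_circle_any_tilt_is_equal(self, circle720):
        res = tilt_experiment(circle720, circle720.axis_frame, 33.0)
        assert res.prediction_tilted.relative_animal == \
            pytest.approx(0.5, abs=1e-4)

    def test_anisotropic_contour_tilt_creates_ucd(self, rng):
        """A 5.67-degree anaphase-like tilt on a flattened, elongated cell
        makes the vegetal side larger; magnitude checked against the
        Monte-Carlo split oracle."""
        contour = make_shape(ShapeSpec("blastomere", radius=25.0,
                                       elongation=1.6, contact_flattening=0.35,
                                       n_vertices=256))
        res = tilt_experiment(contour, contour.axis_frame, 5.67)
        assert res.prediction_untilted.relative_animal == \
            pytest.approx(0.5, abs=1e-6)
        rel = res.prediction_tilted.relative_animal
        assert rel < 0.5
        mc, sigma = mc_split_fraction(
            contour, res.prediction_tilted.cleavage_line, 10**6, rng)
        animal_is_positive = res.prediction_tilted.cleavage_line.signed_distance(
            res.pose_tilted.pole_animal) > 0
        mc_animal = mc if animal_is_positive else 1.0 - mc
        assert abs(rel - mc_animal) < 3 * sigma


class TestChordPivotSweep:
    def test_circle_neutral_everywhere(self, circle720):
        res = chord_pivot_sweep(circle720, circle720.axis_frame,
                                np.arange(0.0, 31.0, 1.0))
        assert np.all(np.isfinite(res.relative_top))
        assert np.allclose(res.relative_top, 0.5, atol=1e-4)

    def test_half_disc_zero_tilt_equal_division(self, half_disc):
        res = chord_pivot_sweep(half_disc, half_disc.axis_frame, [0.0])
        assert res.relative_top[0] == pytest.approx(0.5, abs=1e-4)

    def test_half_disc_closed_form_linear_departure(self, half_disc):
        """While both chord ends lie on the arc, the cut passes through the
        full-disc centre, so relative_top = 1/2 - alpha/180 exactly."""
        angles = np.arange(0.0, 31.0, 1.0)
        res = chord_pivot_sweep(half_disc, half_disc.axis_frame, angles)
        assert np.allclose(res.relative_top, 0.5 - angles / 180.0, atol=2e-4)

    def test_half_disc_continuity(self, half_disc):
        angles = np.arange(0.0, 30.01, 0.1)
        res = chord_pivot_sweep(half_disc, half_disc.axis_frame, angles)
        assert np.all(np.abs(np.diff(res.relative_top)) < 0.01)

    def test_pivot_sits_on_animal_boundary(self, half_disc):
        res = chord_pivot_sweep(half_disc, half_disc.axis_frame, [0.0])
        c = polygon_centroid(half_disc)
        assert res.pivot[0] == pytest.approx(c[0], abs=1e-9)
        assert res.pivot == pytest.approx(
            [c[0], np.sqrt(1 - c[0] ** 2)], abs=1e-4)

    def test_ray_missing_boundary_is_nan(self, half_disc):
        # tilting far toward the flat edge eventually exits without re-entry
        res = chord_pivot_sweep(half_disc, half_disc.axis_frame, [-170.0])
        assert np.isnan(res.relative_top[0])
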