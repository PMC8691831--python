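"""In-silico spindle repositioning and tilt-sweep procedures.

Two virtual experiments performed on a cell contour:

* **Virtual repositioning** — the spindle is first aligned with the
  animal-vegetal (AV) axis and centred along it (plate at the midpoint of
  the axis chord through the centroid); a measured tilt is then applied
  while the spindle is kept centred along its own (tilted) axis. The
  division prediction of both poses quantifies the effect of tilt alone,
  with off-centring excluded.
* **Chord-pivot sweep** — the top (animal) spindle pole is pinned to the
  boundary point where the AV line through the centroid exits the cell;
  the spindle line is swept through a range of tilt angles, the vegetal
  pole tracking the boundary along each ray. The midzone sits at the
  chord midpoint and the relative top area after perpendicular bisection
  is recorded per angle. On a circle this fraction is 0.5 at every angle
  (a chord's perpendicular bisector passes through the centre), while
  anisotropic shapes develop unequal divisions as tilt grows.

"Centred along its axis" is implemented as plate = chord midpoint of the
spindle line, found by fixed-point iteration (rotate about the current
plate, recompute the chord, move the plate to its midpoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, GeometryError
from .geometry2d import COORD_TOL, Contour, Line2, polygon_centroid, rotate
from .spindle_metrics import (
    AxisFrame,
    DivisionPrediction,
    SpindlePose,
    division_prediction,
    line_contour_intersections,
    spindle_angle,
)

#: default spindle length as a fraction of the supporting chord
POLE_FRACTION = 0.8


@dataclass(frozen=True)
class TiltExperimentResult:
    """Paired untilted/tilted virtual-repositioning outcome for one cell."""

    pose_untilted: SpindlePose
    pose_tilted: SpindlePose
    prediction_untilted: DivisionPrediction
    prediction_tilted: DivisionPrediction
    tilt_deg: float


@dataclass(frozen=True)
class SweepResult:
    """Chord-pivot sweep: relative top area per tilt angle.

    Angles where the pivot ray fails to re-enter the shape are NaN.
    """

    angles_deg: np.ndarray
    relative_top: np.ndarray
    pivot: np.ndarray
    shape_id: str


def _chord_about(contour: Contour, line: Line2, t0: float = 0.0):
    """Boundary chord of ``line`` containing coordinate ``t0``; returns (t_lo, t_hi)."""
    ts = [line.coordinate(p) for p in line_contour_intersections(contour, line)]
    lo = [t for t in ts if t <= t0 + COORD_TOL]
    hi = [t for t in ts if t >= t0 - COORD_TOL]
    if not lo or not hi:
        raise GeometryError("line does not span the contour about the reference point")
    return max(lo), min(hi)


def _pose_on_chord(plate: np.ndarray, direction: np.ndarray,
                   chord_length: float, pole_fraction: float) -> SpindlePose:
    half = 0.5 * pole_fraction * chord_length
    return SpindlePose(
        pole_animal=plate + half * direction,
        pole_vegetal=plate - half * direction,
        plate=plate.copy(),
    )


def reposition_centered(contour: Contour, frame: AxisFrame,
                        pole_fraction: float = POLE_FRACTION) -> SpindlePose:
    """Align the spindle with the AV axis and centre it along that axis.

    The plate is the midpoint of the AV-parallel chord through the
    centroid; the poles sit symmetrically about the plate at
    ``pole_fraction`` of the chord length, animal pole toward
    ``frame.av_direction``.
    """
    centroid = polygon_centroid(contour)
    line = Line2(centroid, frame.av_direction)
    t_lo, t_hi = _chord_about(contour, line)
    if t_hi - t_lo <= COORD_TOL:
        raise GeometryError("AV line through the centroid misses the contour")
    plate = centroid + 0.5 * (t_lo + t_hi) * frame.av_direction
    return _pose_on_chord(plate, frame.av_direction, t_hi - t_lo, pole_fraction)


def _tilt_rotation_sign(direction: np.ndarray, frame: AxisFrame) -> float:
    # CCW rotation moves the vegetal pole along rot90(-direction); pick the
    # rotation sense that moves it toward sign_reference
    veg_motion = np.array([direction[1], -direction[0]])
    s = float(np.dot(veg_motion, frame.sign_reference))
    return 1.0 if s >= 0 else -1.0


def apply_tilt_centered(contour: Contour, pose: SpindlePose, tilt_deg: float,
                        frame: AxisFrame | None = None,
                        pole_fraction: float = POLE_FRACTION,
                        tol: float = 1e-9, max_iter: int = 100) -> SpindlePose:
    """Rotate the spindle by ``tilt_deg`` while keeping it chord-centred.

    Positive tilt rotates the vegetal pole toward the frame's
    ``sign_reference`` (frame taken from ``contour.axis_frame`` when not
    given). The plate is re-centred by fixed-point iteration: rotate about
    the current plate, recompute the boundary chord of the tilted line,
    move the plate to the chord midpoint, repeat until the plate moves
    less than ``tol`` um.
    """
    if abs(tilt_deg) >= 90.0:
        raise GeometryError("tilt magnitude must be below 90 degrees")
    if frame is None:
        frame = contour.axis_frame
    if frame is None:
        raise GeometryError("no axis frame available for the tilt sign")
    direction = rotate(pose.direction,
                       _tilt_rotation_sign(pose.direction, frame) * tilt_deg)
    plate = pose.plate.copy()
    residual = np.inf
    for _ in range(max_iter):
        line = Line2(plate, direction)
        t_lo, t_hi = _chord_about(contour, line)
        new_plate = plate + 0.5 * (t_lo + t_hi) * direction
        residual = float(np.linalg.norm(new_plate - plate))
        plate = new_plate
        if residual < tol:
            return _pose_on_chord(plate, direction, t_hi - t_lo, pole_fraction)
    raise ConvergenceError(
        f"plate re-centering did not converge (last move {residual:.3g} um)",
        residual=residual,
    )


def tilt_experiment(contour: Contour, frame: AxisFrame,
                    tilt_deg: float) -> TiltExperimentResult:
    """Run the paired untilted-centred vs tilted-centred scenario."""
    pose0 = reposition_centered(contour, frame)
    pose1 = apply_tilt_centered(contour, pose0, tilt_deg, frame=frame)
    return TiltExperimentResult(
        pose_untilted=pose0,
        pose_tilted=pose1,
        prediction_untilted=division_prediction(contour, pose0),
        prediction_tilted=division_prediction(contour, pose1),
        tilt_deg=float(tilt_deg),
    )


def chord_pivot_sweep(contour: Contour, frame: AxisFrame, angles_deg,
                      shape_id: str = "") -> SweepResult:
    """Sweep the spindle tilt with the top (animal) pole pinned.

    The pivot is the animal-side boundary intersection of the AV line
    through the centroid. For each angle the spindle line leaves the pivot
    rotated by that angle from the AV direction (positive toward
    ``sign_reference``); the vegetal pole is the next boundary intersection
    along the ray, the midzone the chord midpoint, and the cut
    perpendicular to the chord. ``relative_top`` is the animal-side area
    fraction; angles whose ray fails to re-enter the shape yield NaN.
    """
    centroid = polygon_centroid(contour)
    av_line = Line2(centroid, frame.av_direction)
    ts = [av_line.coordinate(p)
          for p in line_contour_intersections(contour, av_line)]
    animal_ts = [t for t in ts if t > COORD_TOL]
    if not animal_ts:
        raise GeometryError("AV line through the centroid has no animal-side exit")
    pivot = centroid + min(animal_ts) * frame.av_direction
    down = -frame.av_direction
    rot_sign = 1.0 if float(np.dot(np.array([-down[1], down[0]]),
                                   frame.sign_reference)) >= 0 else -1.0

    angles = np.asarray(angles_deg, dtype=float)
    rel = np.full(angles.shape, np.nan)
    for i, alpha in enumerate(angles):
        value = _pivot_chord_fraction(contour, pivot, down, rot_sign * alpha)
        if value is None:  # perturb measure-zero vertex grazing and retry
            value = _pivot_chord_fraction(contour, pivot, down,
                                          rot_sign * (alpha + 1e-7))
        if value is not None:
            rel[i] = value
    return SweepResult(angles_deg=angles, relative_top=rel,
                       pivot=pivot, shape_id=shape_id)


def _pivot_chord_fraction(contour: Contour, pivot: np.ndarray,
                          down: np.ndarray, alpha: float) -> float | None:
    ray_dir = rotate(down, alpha)
    line = Line2(pivot, ray_dir)
    ts = sorted(line.coordinate(p)
                for p in line_contour_intersections(contour, line))
    forward = [t for t in ts if t > 1e-7]
    if not forward:
        return None
    vegetal = pivot + min(forward) * ray_dir
    pose = SpindlePose(pole_animal=pivot, pole_vegetal=vegetal)
    try:
        return division_prediction(contour, pose).relative_animal
    except GeometryError:
        return None
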