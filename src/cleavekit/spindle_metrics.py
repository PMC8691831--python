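"""Per-cell spindle quantifications.

Three measurements made on a 2D confocal section of a mitotic blastomere:

* **spindle angle** — the signed acute angle between the pole-pole line and
  the animal-vegetal (AV) axis. The sign is positive when the vegetal pole
  is displaced from the AV line toward the frame's ``sign_reference``
  (e.g. toward the posterior pole in sagittal views, away from the midline
  in transversal views).
* **centering ratio** — the position of the chromosomal plate along the
  spindle axis between the two cortical intersections, expressed as
  d_animal / (d_animal + d_vegetal). 0.5 means a centred spindle; above 0.5
  the spindle is off-centred toward the vegetal pole. The raw edge
  distances are exposed so the plain quotient d_animal/d_vegetal is
  recoverable.
* **division prediction** — the cleavage plane is placed perpendicular to
  the spindle at the chromosomal plate (midzone) and the relative animal
  area of the bisected contour is reported; 0.5 means an equal division
  and values below 0.5 mean the vegetal daughter is larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AmbiguousSideError, GeometryError, InvalidPoseError
from .geometry2d import (
    COORD_TOL,
    Contour,
    Line2,
    _as_point,
    line_contour_intersections,
    polygon_area,
    rot90,
    split_by_line,
)


@dataclass(frozen=True)
class AxisFrame:
    """Animal-vegetal reference frame of a 2D section.

    ``av_direction`` points from the vegetal toward the animal pole;
    ``sign_reference`` defines which lateral side counts as a positive tilt.
    """

    origin: np.ndarray
    av_direction: np.ndarray
    sign_reference: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_point(self.origin))
        for name in ("av_direction", "sign_reference"):
            v = _as_point(getattr(self, name))
            n = np.linalg.norm(v)
            if n < COORD_TOL:
                raise ValueError(f"{name} must be non-zero")
            object.__setattr__(self, name, v / n)
        av, sr = self.av_direction, self.sign_reference
        cross = abs(float(av[0] * sr[1] - av[1] * sr[0]))
        if cross < COORD_TOL:
            raise ValueError("av_direction and sign_reference must not be parallel")


@dataclass(frozen=True)
class SpindlePose:
    """Two spindle-pole points plus the chromosomal-plate point.

    The plate must lie on the pole-pole segment (within 1e-9 um); it
    defaults to the segment midpoint when not measured.
    """

    pole_animal: np.ndarray
    pole_vegetal: np.ndarray
    plate: np.ndarray | None = None

    def __post_init__(self):
        pa = _as_point(self.pole_animal)
        pv = _as_point(self.pole_vegetal)
        object.__setattr__(self, "pole_animal", pa)
        object.__setattr__(self, "pole_vegetal", pv)
        if np.linalg.norm(pa - pv) <= COORD_TOL:
            raise InvalidPoseError("spindle poles coincide")
        if self.plate is None:
            object.__setattr__(self, "plate", 0.5 * (pa + pv))
        else:
            p = _as_point(self.plate)
            seg = pv - pa
            t = np.clip(np.dot(p - pa, seg) / np.dot(seg, seg), 0.0, 1.0)
            if np.linalg.norm(p - (pa + t * seg)) > 1e-6:
                raise InvalidPoseError("plate does not lie on the pole-pole segment")
            object.__setattr__(self, "plate", p)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector pointing from the vegetal toward the animal pole."""
        d = self.pole_animal - self.pole_vegetal
        return d / np.linalg.norm(d)

    @property
    def axis_line(self) -> Line2:
        """The infinite spindle line, oriented vegetal -> animal."""
        return Line2(self.plate, self.direction)


@dataclass(frozen=True)
class CenteringResult:
    """Plate position between the two cortical intersections.

    value = d_animal / (d_animal + d_vegetal); 0.5 is centred, above 0.5
    is off-centred toward the vegetal pole.
    """

    value: float
    d_animal: float
    d_vegetal: float


@dataclass(frozen=True)
class DivisionPrediction:
    """Predicted bisection of the cell by the cleavage line at the midzone."""

    cleavage_line: Line2
    area_animal: float
    area_vegetal: float

    @property
    def relative_animal(self) -> float:
        return self.area_animal / (self.area_animal + self.area_vegetal)


def spindle_angle(pose: SpindlePose, frame: AxisFrame) -> float:
    """Signed spindle tilt relative to the AV axis, in degrees in (-90, 90].

    The magnitude is the minimal angle between the (apolar) pole-pole line
    and the AV direction; the sign is positive when the vegetal pole
    deviates from the AV line toward ``frame.sign_reference``. A spindle
    perpendicular to the axis reports +90.
    """
    u = pose.direction  # vegetal -> animal
    av = frame.av_direction
    cross = u[0] * av[1] - u[1] * av[0]
    magnitude = np.degrees(np.arctan2(abs(cross), abs(np.dot(u, av))))
    # displacement of the vegetal pole off the AV line through the animal pole
    w = pose.pole_vegetal - pose.pole_animal
    perp = w - np.dot(w, frame.av_direction) * frame.av_direction
    s = float(np.dot(perp, frame.sign_reference))
    if magnitude > 90.0 - 1e-12:
        return 90.0
    return float(magnitude if s >= 0 else -magnitude)


def centering_ratio(contour: Contour, pose: SpindlePose) -> CenteringResult:
    """Plate position along the spindle axis between the cell edges.

    Edge distances are measured on the infinite spindle line from the
    chromosomal plate to the nearest boundary intersection on the
    animal-pole side and on the vegetal-pole side; for non-convex contours
    this matches a ruler measurement on the section.
    """
    line = pose.axis_line
    ts = [line.coordinate(p) for p in line_contour_intersections(contour, line)]
    animal = [t for t in ts if t > COORD_TOL]
    vegetal = [-t for t in ts if t < -COORD_TOL]
    if not animal:
        raise GeometryError("spindle line does not exit the contour on the animal side")
    if not vegetal:
        raise GeometryError("spindle line does not exit the contour on the vegetal side")
    d_a, d_v = min(animal), min(vegetal)
    return CenteringResult(value=d_a / (d_a + d_v), d_animal=d_a, d_vegetal=d_v)


def division_prediction(contour: Contour, pose: SpindlePose) -> DivisionPrediction:
    """Bisect the contour perpendicular to the spindle at its midzone.

    The cleavage line passes through the chromosomal plate, perpendicular
    to the pole-pole direction; the animal side is the one containing the
    animal pole. Relative animal area below 0.5 means the vegetal daughter
    is predicted larger.
    """
    cleavage = Line2(pose.plate, rot90(pose.direction))
    side = cleavage.signed_distance(pose.pole_animal)
    if abs(side) <= COORD_TOL:
        raise AmbiguousSideError("animal pole lies on the cleavage line")
    split = split_by_line(contour, cleavage)
    if side > 0:
        area_animal, area_vegetal = split.area_positive, split.area_negative
    else:
        area_animal, area_vegetal = split.area_negative, split.area_positive
    return DivisionPrediction(cleavage_line=cleavage,
                              area_animal=area_animal, area_vegetal=area_vegetal)
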