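"""Planar polygon geometry for cell-contour analysis.

Cell outlines are closed simple polygons in Cartesian micrometres, stored
counter-clockwise with implicit closure (the first vertex is not repeated).
By convention the y axis increases toward the animal pole. All public angle
arguments and results are in degrees; radians are used internally only.

Polygon splitting and line-boundary intersection are delegated to shapely;
areas, centroids, and shape descriptors are computed directly from the
vertex list (shoelace formulas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .errors import InvalidContourError, NoSplitError

#: coordinates closer than this (um) are considered coincident
COORD_TOL = 1e-9
#: polygon areas below this (um^2) are considered degenerate
AREA_TOL = 1e-12


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(2)
    return a


def rot90(v: np.ndarray) -> np.ndarray:
    """Rotate a 2D vector by +90 degrees (counter-clockwise)."""
    return np.array([-v[1], v[0]])


def rotate(v: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a 2D vector counter-clockwise by ``angle_deg`` degrees."""
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


@dataclass(frozen=True)
class Line2:
    """An infinite oriented line: anchor point plus unit direction.

    The positive side of the line is the left side of ``direction``
    (normal = direction rotated by +90 degrees).
    """

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", _as_point(self.point))
        d = _as_point(self.direction)
        n = np.linalg.norm(d)
        if n < COORD_TOL:
            raise ValueError("line direction must be non-zero")
        object.__setattr__(self, "direction", d / n)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal pointing into the positive half-plane."""
        return rot90(self.direction)

    def signed_distance(self, p) -> float:
        """Perpendicular signed distance of ``p`` from the line (+ = left)."""
        return float(np.dot(_as_point(p) - self.point, self.normal))

    def coordinate(self, p) -> float:
        """Signed coordinate of the projection of ``p`` along the line."""
        return float(np.dot(_as_point(p) - self.point, self.direction))


class Contour:
    """Closed simple polygon outline of a cell (vertices in um, CCW).

    Parameters
    ----------
    vertices : array-like of shape (n, 3) or list of pairs
        Ordered polygon vertices. A duplicated closing vertex is accepted
        and removed; clockwise input is reversed to counter-clockwise.
    axis_frame : AxisFrame, optional
        Animal-vegetal reference frame attached to this cell.
    """

    __slots__ = ("_vertices", "axis_frame", "_polygon", "_area", "_centroid")

    def __init__(self, vertices, axis_frame=None):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidContourError("vertices must be an (n, 2) array")
        if len(v) >= 2 and np.linalg.norm(v[0] - v[-1]) < COORD_TOL:
            v = v[:-1]
        if len(v) < 3:
            raise InvalidContourError("a contour needs at least 3 vertices")
        signed = _shoelace(v)
        if abs(signed) < AREA_TOL:
            raise InvalidContourError("degenerate contour: area below 1e-12 um^2")
        if signed < 0:
            v = v[::-1]
        poly = Polygon(v)
        if not poly.is_valid:
            raise InvalidContourError("contour is not a simple polygon")
        self._vertices = v
        self._vertices.setflags(write=False)
        self.axis_frame = axis_frame
        self._polygon = poly
        self._area = abs(signed)
        self._centroid = None

    @property
    def vertices(self) -> np.ndarray:
        return self._vertices

    @property
    def n_vertices(self) -> int:
        return len(self._vertices)

    @property
    def polygon(self) -> Polygon:
        """The shapely polygon backing this contour."""
        return self._polygon

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self._vertices, self._vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def with_frame(self, axis_frame) -> "Contour":
        return Contour(self._vertices, axis_frame=axis_frame)

    def __repr__(self):
        return f"Contour(n={self.n_vertices}, area={self._area:.4g} um^2)"


@dataclass
class SplitResult:
    """Outcome of cutting a contour with an infinite line.

    Pieces on the positive side are those left of the line direction.
    Per-side areas are sums over pieces; they conserve the parent area.
    """

    pieces_positive: list = field(default_factory=list)
    pieces_negative: list = field(default_factory=list)
    area_positive: float = 0.0
    area_negative: float = 0.0


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_area(contour: Contour) -> float:
    """Area of the contour in um^2 (shoelace on the CCW vertex list)."""
    return contour._area


def polygon_centroid(contour: Contour) -> np.ndarray:
    """Area-weighted centroid (centre of mass of the uniform lamina)."""
    if contour._centroid is None:
        v = contour.vertices
        x, y = v[:, 0], v[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * cross.sum()
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        contour._centroid = np.array([cx, cy])
    return contour._centroid.copy()


def circularity(contour: Contour) -> float:
    """Isoperimetric quotient 4*pi*A/P^2 in (0, 1]; 1 in the circular limit."""
    p = contour.perimeter
    return 4.0 * np.pi * polygon_area(contour) / (p * p)


def _long_segment(contour: Contour, line: Line2) -> LineString:
    # a segment guaranteed to span the polygon along the line
    minx, miny, maxx, maxy = contour.polygon.bounds
    c = np.array([(minx + maxx) / 2.0, (miny + maxy) / 2.0])
    reach = np.hypot(maxx - minx, maxy - miny) + 1.0
    base = line.point + line.coordinate(c) * line.direction
    return LineString([base - reach * line.direction, base + reach * line.direction])


def line_contour_intersections(contour: Contour, line: Line2) -> list[np.ndarray]:
    """All intersections of an infinite line with the polygon boundary.

    Points are deduplicated within 1e-9 um and sorted by signed coordinate
    along the line direction. Collinear boundary-edge overlaps contribute
    their endpoints. Returns an empty list when the line misses the polygon.
    """
    seg = _long_segment(contour, line)
    inter = contour.polygon.boundary.intersection(seg)
    pts: list[np.ndarray] = []
    for geom in getattr(inter, "geoms", [inter]):
        if geom.is_empty:
            continue
        if geom.geom_type == "Point":
            pts.append(np.array([geom.x, geom.y]))
        else:  # LineString from a collinear edge overlap
            pts.extend(np.asarray(geom.coords))
    if not pts:
        return []
    pts.sort(key=line.coordinate)
    out = [pts[0]]
    for p in pts[1:]:
        if np.linalg.norm(p - out[-1]) > COORD_TOL:
            out.append(p)
    return out


def _halfplane(contour: Contour, line: Line2, side: int) -> Polygon:
    minx, miny, maxx, maxy = contour.polygon.bounds
    c = np.array([(minx + maxx) / 2.0, (miny + maxy) / 2.0])
    reach = 2.0 * np.hypot(maxx - minx, maxy - miny) + 1.0
    base = line.point + line.coordinate(c) * line.direction
    d, n = line.direction, side * line.normal
    return Polygon(
        [
            base - reach * d,
            base + reach * d,
            base + reach * d + reach * n,
            base - reach * d + reach * n,
        ]
    )


def split_by_line(contour: Contour, line: Line2) -> SplitResult:
    """Cut the contour with an infinite line into per-side pieces.

    Non-convex contours may yield several pieces on a side. Raises
    :class:`NoSplitError` when the line misses the interior (including a
    tangency at a single vertex). Piece areas conserve the parent area.
    """
    result = SplitResult()
    for side, pieces, attr in (
        (+1, result.pieces_positive, "area_positive"),
        (-1, result.pieces_negative, "area_negative"),
    ):
        clipped = contour.polygon.intersection(_halfplane(contour, line, side))
        total = 0.0
        for geom in getattr(clipped, "geoms", [clipped]):
            if geom.is_empty or geom.geom_type != "Polygon" or geom.area <= AREA_TOL:
                continue
            pieces.append(Contour(np.asarray(geom.exterior.coords)[:-1],
                                  axis_frame=contour.axis_frame))
            total += geom.area
        setattr(result, attr, total)
    parent = polygon_area(contour)
    if result.area_positive <= AREA_TOL * max(1.0, parent) or \
            result.area_negative <= AREA_TOL * max(1.0, parent):
        raise NoSplitError("line does not pass through the contour interior")
    return result
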