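"""Independent brute-force oracles used to check the geometric operations.

These deliberately avoid the code paths they validate: Monte-Carlo
point-in-polygon area fractions, dense boundary ray casting, brute-force
segment-segment intersection, and voxel-counting volume fractions on
analytic solids.
"""

from __future__ import annotations

import numpy as np
import shapely


def mc_split_fraction(contour, line, n_points: int, rng):
    """Monte-Carlo estimate of the positive-side area fraction of a cut.

    Returns (fraction, sigma) where sigma is the binomial standard error
    of the fraction estimate among in-polygon samples.
    """
    minx, miny, maxx, maxy = contour.polygon.bounds
    xs = rng.uniform(minx, maxx, n_points)
    ys = rng.uniform(miny, maxy, n_points)
    inside = shapely.contains_xy(contour.polygon, xs, ys)
    n_in = int(inside.sum())
    side = ((xs[inside] - line.point[0]) * line.normal[0]
            + (ys[inside] - line.point[1]) * line.normal[1]) > 0
    frac = side.sum() / n_in
    sigma = np.sqrt(max(frac * (1.0 - frac), 1e-12) / n_in)
    return float(frac), float(sigma)


def mc_polygon_area(contour, n_points: int, rng):
    """Monte-Carlo polygon area estimate with its standard error."""
    minx, miny, maxx, maxy = contour.polygon.bounds
    box = (maxx - minx) * (maxy - miny)
    xs = rng.uniform(minx, maxx, n_points)
    ys = rng.uniform(miny, maxy, n_points)
    p = shapely.contains_xy(contour.polygon, xs, ys).mean()
    return box * p, box * np.sqrt(p * (1 - p) / n_points)


def segment_intersections(vertices: np.ndarray, p0, p1):
    """Brute-force intersections of segment p0-p1 with every polygon edge."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    pts = []
    n = len(vertices)
    for i in range(n):
        a, b = vertices[i], vertices[(i + 1) % n]
        e = b - a
        denom = d[0] * e[1] - d[1] * e[0]
        if abs(denom) < 1e-14:
            continue
        rhs = a - p0
        t = (rhs[0] * e[1] - rhs[1] * e[0]) / denom
        u = (rhs[0] * d[1] - rhs[1] * d[0]) / denom
        if -1e-12 <= u <= 1 + 1e-12 and -1e-12 <= t <= 1 + 1e-12:
            pts.append(p0 + t * d)
    # dedup
    out = []
    for p in sorted(pts, key=lambda q: float(np.dot(q - p0, d))):
        if not out or np.linalg.norm(p - out[-1]) > 1e-9:
            out.append(p)
    return out


def raycast_edge_distances(contour, origin, direction, n_samples: int = 200000):
    """Nearest boundary hit along +-direction by dense boundary sampling."""
    boundary = contour.polygon.exterior
    ts = np.linspace(0.0, boundary.length, n_samples, endpoint=False)
    pts = np.asarray([boundary.interpolate(float(t)).coords[0] for t in ts])
    rel = pts - np.asarray(origin, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    along = rel @ d
    perp = np.abs(rel @ np.array([-d[1], d[0]]))
    on_line = perp < 2.0 * boundary.length / n_samples
    fwd = along[on_line & (along > 1e-9)]
    back = -along[on_line & (along < -1e-9)]
    return (fwd.min() if fwd.size else np.inf,
            back.min() if back.size else np.inf)


def voxel_ellipsoid_plane_fraction(semi_axes, plane_point, plane_normal,
                                   n_voxels: int = 128):
    """Voxel-counting positive-side volume fraction of an origin-centred
    axis-aligned ellipsoid cut by a plane."""
    a, b, c = semi_axes
    lin = lambda h, m: (np.arange(m) + 0.5) / m * 2 * h - h
    x = lin(a, n_voxels)[:, None, None]
    y = lin(b, n_voxels)[None, :, None]
    z = lin(c, n_voxels)[None, None, :]
    inside = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    p = np.asarray(plane_point, float)
    n = np.asarray(plane_normal, float)
    n = n / np.linalg.norm(n)
    side = (x - p[0]) * n[0] + (y - p[1]) * n[1] + (z - p[2]) * n[2] > 0
    n_in = inside.sum()
    return float((inside & side).sum() / n_in)


def circular_segment_area(h: float, r: float = 1.0) -> float:
    """Area of the disc segment above the chord y = h (closed form)."""
    return r * r * np.arccos(h / r) - h * np.sqrt(r * r - h * h)


def random_star_polygon(rng, n_min=6, n_max=16, r_min=0.5, r_max=2.0):
    """Random simple (star-shaped) polygon around a random centre."""
    n = int(rng.integers(n_min, n_max + 1))
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    if np.min(np.diff(angles, append=angles[0] + 2 * np.pi)) < 1e-3:
        angles = 2 * np.pi * (np.arange(n) + rng.uniform(0.1, 0.9, n)) / n
    radii = rng.uniform(r_min, r_max, n)
    center = rng.uniform(-1, 1, 2)
    return center + np.column_stack([radii * np.cos(angles),
                                     radii * np.sin(angles)])
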