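"""Deterministic parametric cell-shape generators.

Four families cover the analysis shapes: a circle (isotropic reference),
a half-disc (the constrained, anisotropic reference whose flat edge stands
for a cell-cell contact), an ellipse, and an idealized blastomere profile —
a superellipse elongated along the animal-vegetal (AV) axis with one
lateral side flattened by a cell-cell contact and an optional
animal/vegetal width skew.

Shapes are generated in a canonical frame (AV axis = +y, positive-tilt
side = +x, centred on the origin) and then rotated by ``orientation_deg``;
the matching :class:`~cleavekit.spindle_metrics.AxisFrame` is attached to
the returned contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .geometry2d import Contour, rotate
from .spindle_metrics import AxisFrame

KINDS = ("circle", "half_disc", "ellipse", "blastomere")


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one generated shape.

    For ``blastomere``, ``radius`` is the half-width (um) perpendicular to
    the AV axis, ``elongation`` the AV length over width ratio,
    ``contact_flattening`` the fraction of the half-width cut off by the
    flat contact on the negative-x side, and ``asymmetry`` a linear skew
    of the width along the AV axis (0 = symmetric). With elongation 1,
    flattening 0, asymmetry 0 and exponent 2 the profile is the circle.
    """

    kind: str
    radius: float = 1.0
    semi_axes: tuple[float, float] | None = None
    n_vertices: int = 720
    orientation_deg: float = 0.0
    elongation: float = 1.0
    contact_flattening: float = 0.0
    asymmetry: float = 0.0
    exponent: float = 2.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ParameterError(f"unknown shape kind {self.kind!r}")
        if self.n_vertices < 16:
            raise ParameterError("n_vertices must be >= 16")
        if self.radius <= 0:
            raise ParameterError("radius must be positive")
        if self.kind == "ellipse":
            ax = self.semi_axes
            if ax is None or len(ax) != 2 or ax[0] <= 0 or ax[1] <= 0:
                raise ParameterError("ellipse needs two positive semi_axes")
        if not 0.0 <= self.contact_flattening < 1.0:
            raise ParameterError("contact_flattening must lie in [0, 1)")
        if self.elongation <= 0:
            raise ParameterError("elongation must be positive")
        if self.exponent < 1.0:
            raise ParameterError("exponent must be >= 1 for a convex profile")


def _circle_vertices(radius: float, n: int) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / n
    return radius * np.column_stack([np.cos(t), np.sin(t)])


def _half_disc_vertices(radius: float, n: int) -> np.ndarray:
    # flat edge along the y axis (parallel to AV), arc bulging toward +x;
    # CCW from the bottom of the flat edge through the arc to the top
    t = np.linspace(-0.5 * np.pi, 0.5 * np.pi, n)
    return radius * np.column_stack([np.cos(t), np.sin(t)])


def _superellipse_vertices(a: float, b: float, p: float, n: int) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / n
    x = np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / p)
    y = np.sign(np.sin(t)) * np.abs(np.sin(t)) ** (2.0 / p)
    return np.column_stack([a * x, b * y])


def make_shape(spec: ShapeSpec) -> Contour:
    """Build the CCW polygon for ``spec`` and attach its axis frame."""
    if spec.kind == "circle":
        v = _circle_vertices(spec.radius, spec.n_vertices)
    elif spec.kind == "half_disc":
        v = _half_disc_vertices(spec.radius, spec.n_vertices)
    elif spec.kind == "ellipse":
        a, b = spec.semi_axes
        v = _superellipse_vertices(a, b, 2.0, spec.n_vertices)
    else:  # blastomere
        a = spec.radius
        b = spec.radius * spec.elongation
        v = _superellipse_vertices(a, b, spec.exponent, spec.n_vertices)
        if spec.asymmetry != 0.0:
            # taper the width linearly along the AV axis
            v[:, 0] *= 1.0 + 0.5 * spec.asymmetry * (v[:, 1] / b)
        if spec.contact_flattening > 0.0:
            # flatten the negative-x side against a straight contact
            v[:, 0] = np.maximum(v[:, 0], -a * (1.0 - spec.contact_flattening))
    if spec.orientation_deg != 0.0:
        t = np.deg2rad(spec.orientation_deg)
        c, s = np.cos(t), np.sin(t)
        v = v @ np.array([[c, s], [-s, c]])
    frame = AxisFrame(
        origin=np.zeros(2),
        av_direction=rotate(np.array([0.0, 1.0]), spec.orientation_deg),
        sign_reference=rotate(np.array([1.0, 0.0]), spec.orientation_deg),
    )
    return Contour(v, axis_frame=frame)


def shape_anisotropy(contour: Contour, frame: AxisFrame) -> float:
    """Extent of the contour along the AV axis over its perpendicular extent."""
    v = contour.vertices
    along = v @ frame.av_direction
    perp = v @ np.array([-frame.av_direction[1], frame.av_direction[0]])
    return float((along.max() - along.min()) / (perp.max() - perp.min()))
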