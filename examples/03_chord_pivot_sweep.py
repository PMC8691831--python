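"""Chord-pivot tilt sweep on an isotropic vs an anisotropic shape.

The top (animal) spindle pole is pinned to the cell boundary and the
spindle is swept through increasing tilt angles; the vegetal pole tracks
the boundary, the midzone sits at the chord midpoint, and the cell is cut
perpendicular to the chord. The isotropic circle divides equally at every
angle; the half-disc (flat edge parallel to the untilted spindle, a
stand-in for a cell-cell contact) develops unequal divisions as tilt
grows.
"""

import numpy as np

from cleavekit import ShapeSpec, chord_pivot_sweep, make_shape

angles = np.arange(0.0, 31.0, 5.0)
circle = make_shape(ShapeSpec("circle", radius=10.0, n_vertices=720))
half_disc = make_shape(ShapeSpec("half_disc", radius=10.0, n_vertices=720))

sw_circle = chord_pivot_sweep(circle, circle.axis_frame, angles, "circle")
sw_half = chord_pivot_sweep(half_disc, half_disc.axis_frame, angles,
                            "half_disc")

print("tilt_deg  circle  half_disc")
for a, rc, rh in zip(angles, sw_circle.relative_top, sw_half.relative_top):
    print(f"{a:7.1f}  {rc:.4f}     {rh:.4f}")

print()
print("relative top area: 0.5 = equal division, below 0.5 = bottom")
print("(vegetal) side larger. On the half-disc the value follows")
print("0.5 - tilt/180 while both chord ends stay on the arc, because the")
print("perpendicular bisector of an arc chord passes through the centre")
print("of the full disc.")
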