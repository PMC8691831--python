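"""Measure spindle pose on a single blastomere section.

Builds an anisotropic blastomere contour (elongated along the
animal-vegetal axis, one side flattened by a cell-cell contact), places a
tilted, slightly off-centred spindle in it, and computes the three
per-cell metrics: spindle angle, centering ratio, and the division
prediction by perpendicular bisection at the midzone.
"""

import numpy as np

from cleavekit import (
    ShapeSpec,
    SpindlePose,
    centering_ratio,
    division_prediction,
    make_shape,
    spindle_angle,
)
from cleavekit.geometry2d import rotate

contour = make_shape(ShapeSpec("blastomere", radius=25.0, elongation=1.6,
                               contact_flattening=0.35, n_vertices=360))
frame = contour.axis_frame

# a spindle tilted 21.3 deg from the AV axis, vegetal pole toward +x,
# plate pushed slightly toward the vegetal side
direction = rotate(frame.av_direction, 21.3)
plate = np.array([0.0, -2.0])
pose = SpindlePose(pole_animal=plate + 12 * direction,
                   pole_vegetal=plate - 12 * direction, plate=plate)

angle = spindle_angle(pose, frame)
cen = centering_ratio(contour, pose)
pred = division_prediction(contour, pose)

print(f"spindle angle vs AV axis : {angle:+.2f} deg")
print(f"centering ratio          : {cen.value:.3f} "
      f"(d_animal={cen.d_animal:.1f} um, d_vegetal={cen.d_vegetal:.1f} um)")
print(f"relative animal area     : {pred.relative_animal:.3f}")
print()
print("A centering ratio above 0.5 means the plate sits closer to the")
print("vegetal cortex; a relative animal area below 0.5 predicts the")
print("vegetal daughter will be the larger one.")
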