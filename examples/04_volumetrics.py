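"""3D quantification: volume, sphericity and daughter-volume ratio.

Builds an ellipsoidal cell mesh (elongated along the animal-vegetal
z axis), measures its volume and sphericity, then cuts it with a tilted
cleavage plane and reports the relative animal daughter volume.
"""

import numpy as np
import trimesh

from cleavekit import (
    TriMesh,
    plane_bisect_mesh,
    relative_daughter_volume,
    volume_report,
)

sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
semi_axes = np.array([20.0, 20.0, 32.0])  # um; AV axis = z
cell = TriMesh(np.asarray(sphere.vertices) * semi_axes, sphere.faces)

rep = volume_report(cell)
print(f"cell volume      : {rep['volume']:,.0f} um^3")
print(f"surface area     : {rep['surface_area']:,.0f} um^2")
print(f"sphericity       : {rep['sphericity']:.3f}  (1 = perfect sphere)")

# cleavage plane slightly below the equator and tilted 21.3 deg
normal = np.array([np.sin(np.deg2rad(21.3)), 0.0, np.cos(np.deg2rad(21.3))])
v_animal, v_vegetal = plane_bisect_mesh(cell, point=(0, 0, -2.0),
                                        normal=normal)
ratio = relative_daughter_volume(v_animal, v_vegetal)
print(f"animal daughter  : {v_animal:,.0f} um^3")
print(f"vegetal daughter : {v_vegetal:,.0f} um^3")
print(f"relative animal daughter volume: {ratio:.3f}")
print()
print("0.5 would be an equal division; a value above 0.5 means the")
print("animal daughter is larger, below 0.5 the vegetal one.")
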