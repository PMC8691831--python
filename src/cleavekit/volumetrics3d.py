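"""3D cell-body quantifications: volume, sphericity, plane bisection.

Reconstructed cells are closed triangle meshes (um). Volume and surface
area come from the divergence theorem on the oriented surface; sphericity
is the standard pi^(1/3) (6V)^(2/3) / A, equal to 1 for a sphere and
decreasing with shape anisotropy (the quantity used to score mitotic
rounding). Plane bisection yields the two daughter volumes used for the
relative animal daughter volume.

Half-body volumes are computed by slicing the surface open at the plane
and evaluating the divergence-theorem sum with the reference point placed
on the cutting plane: every face of the (virtual) planar cap is then
coplanar with the reference point and contributes exactly zero signed
volume, so no cap triangulation is required.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .errors import MeshIntegrityError, NoSplitError, ParameterError


class TriMesh:
    """Closed, consistently outward-oriented triangle mesh of a cell.

    Wraps a :class:`trimesh.Trimesh` (no automatic processing). The
    constructor enforces watertightness, consistent winding and positive
    enclosed volume.
    """

    __slots__ = ("_mesh",)

    def __init__(self, vertices, faces):
        mesh = trimesh.Trimesh(vertices=np.asarray(vertices, dtype=float),
                               faces=np.asarray(faces, dtype=int),
                               process=False)
        if not mesh.is_watertight:
            raise MeshIntegrityError("mesh is not closed (open edges present)")
        if not mesh.is_winding_consistent:
            raise MeshIntegrityError("mesh faces are not consistently oriented")
        if mesh.volume <= 0:
            raise MeshIntegrityError("mesh is inward-oriented (non-positive volume)")
        self._mesh = mesh

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self._mesh.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self._mesh.faces)

    @property
    def trimesh(self) -> trimesh.Trimesh:
        return self._mesh

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh) -> "TriMesh":
        return cls(mesh.vertices, mesh.faces)

    @classmethod
    def icosphere(cls, radius: float = 1.0, subdivisions: int = 4) -> "TriMesh":
        return cls.from_trimesh(trimesh.creation.icosphere(
            subdivisions=subdivisions, radius=radius))

    @classmethod
    def load(cls, path) -> "TriMesh":
        """Read an ASCII OFF or PLY mesh file."""
        mesh = trimesh.load_mesh(str(path), process=False)
        return cls(mesh.vertices, mesh.faces)

    def save(self, path) -> None:
        """Write the mesh as ASCII OFF or PLY, by file extension."""
        path = str(path)
        if path.endswith(".ply"):
            data = trimesh.exchange.ply.export_ply(self._mesh, encoding="ascii")
            with open(path, "wb") as fh:
                fh.write(data)
        elif path.endswith(".off"):
            with open(path, "w") as fh:
                fh.write(trimesh.exchange.off.export_off(self._mesh))
        else:
            raise ParameterError("mesh export supports .off and .ply only")

    def __repr__(self):
        return (f"TriMesh(v={len(self._mesh.vertices)}, "
                f"f={len(self._mesh.faces)})")


def _signed_volume(vertices: np.ndarray, faces: np.ndarray,
                   origin: np.ndarray) -> float:
    """Divergence-theorem volume of an oriented surface about ``origin``."""
    tri = vertices[faces] - origin
    return float(np.einsum("ij,ij->i", tri[:, 0],
                           np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume in um^3 (positive for outward orientation)."""
    return _signed_volume(mesh.vertices, mesh.faces, np.zeros(3))


def surface_area(mesh: TriMesh) -> float:
    """Total surface area in um^2."""
    return float(mesh.trimesh.area)


def sphericity(mesh: TriMesh) -> float:
    """pi^(1/3) (6V)^(2/3) / A — 1 for a sphere, smaller for any other shape."""
    v = mesh_volume(mesh)
    return float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0)
                 / surface_area(mesh))


def volume_report(mesh: TriMesh) -> dict:
    """Volume, surface area and sphericity of one cell as a plain dict."""
    v, a = mesh_volume(mesh), surface_area(mesh)
    return {
        "volume": v,
        "surface_area": a,
        "sphericity": float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a),
    }


def relative_daughter_volume(v_animal: float, v_vegetal: float) -> float:
    """Animal daughter volume over total daughter volume, in (0, 1).

    0.5 means an equal division; below 0.5 the vegetal daughter is larger.
    """
    if v_animal <= 0 or v_vegetal <= 0:
        raise ParameterError("daughter volumes must be positive")
    return v_animal / (v_animal + v_vegetal)


def plane_bisect_mesh(mesh: TriMesh, point, normal) -> tuple[float, float]:
    """Volumes of the two half-bodies cut by a plane (positive side first).

    The positive side is the one the ``normal`` points into. Raises
    :class:`NoSplitError` when the plane misses the mesh. The two volumes
    sum to the mesh volume within 1e-6 relative.
    """
    point = np.asarray(point, dtype=float).reshape(3)
    normal = np.asarray(normal, dtype=float).reshape(3)
    n = np.linalg.norm(normal)
    if n == 0:
        raise ParameterError("plane normal must be non-zero")
    normal = normal / n
    total = mesh_volume(mesh)
    volumes = []
    for sign in (+1.0, -1.0):
        half = trimesh.intersections.slice_mesh_plane(
            mesh.trimesh, plane_normal=sign * normal, plane_origin=point,
            cap=False)
        if half is None or len(half.faces) == 0:
            volumes.append(0.0)
            continue
        # reference point on the plane: the open cross-section contributes 0
        volumes.append(_signed_volume(np.asarray(half.vertices),
                                      np.asarray(half.faces), point))
    v_pos, v_neg = volumes
    if v_pos <= 1e-12 * total or v_neg <= 1e-12 * total:
        raise NoSplitError("plane does not pass through the mesh interior")
    return v_pos, v_neg
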