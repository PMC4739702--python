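"""Core triangle-mesh container.

A :class:`TriangleMesh` is the unit of analysis for every topographic
metric in this package: an ordered array of 3D vertex coordinates plus an
ordered array of triangular face index triples (0-based).  Length units are
arbitrary (typically mm for scanned specimens); all metrics are either
dimensionless or reported in squared length units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MeshError(ValueError):
    """Raised when mesh data violates the triangle-mesh invariants."""


@dataclass
class TriangleMesh:
    """Triangulated polygon surface mesh.

    Parameters
    ----------
    vertices : (V, 3) float array
        XYZ coordinates in file order.
    faces : (F, 3) int array
        0-based vertex index triples in file order.
    name : str
        Source identifier (filename stem for meshes read from disk).
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (F, 3) array of vertex triples")

    # -- size accessors -------------------------------------------------
    @property
    def vertex_count(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def face_count(self) -> int:
        return int(self.faces.shape[0])

    def validate(self) -> "TriangleMesh":
        """Check the analyzable-mesh invariants, returning self.

        Raises
        ------
        MeshError
            If the mesh is empty, an index is out of range, or a face
            repeats a vertex index.
        """
        if self.vertex_count < 3:
            raise MeshError(f"mesh needs >= 3 vertices, has {self.vertex_count}")
        if self.face_count < 1:
            raise MeshError("mesh needs >= 1 face")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.vertex_count:
            raise MeshError("face index out of range [0, vertex_count)")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise MeshError("face with repeated vertex index")
        return self

    def copy(self, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(),
            self.name if name is None else name,
        )

    def face_coordinates(self) -> np.ndarray:
        """Return the (F, 3, 3) array of per-face corner coordinates."""
        return self.vertices[self.faces]
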