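"""Geometric primitives shared by all topographic metrics.

Face/vertex normals, triangle areas, edge adjacency, boundary detection,
rigid transforms, centroid translation, and the optional implicit-fairing
smooth.  Everything downstream (DNE, RFI, OPCR) builds on these.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .mesh import MeshError, TriangleMesh

#: Faces whose doubled area (cross-product magnitude) falls below this are
#: degenerate (collinear or coincident vertices) and are excluded from all
#: metrics with a warning.  Units: squared mesh length units.
DEGENERATE_AREA_EPSILON = 1e-12


@dataclass
class NormalField:
    """Per-face and per-vertex unit normals (the discrete normal map).

    ``degenerate_faces`` lists faces with near-zero area; their normals are
    zero vectors.  ``bad_vertices`` lists vertices whose incident face
    normals averaged to (numerically) zero length — opposing faces cancel —
    whose normals are likewise zero and untrustworthy.
    """

    face_normals: np.ndarray        # (F, 3)
    face_areas: np.ndarray          # (F,)
    vertex_normals: np.ndarray      # (V, 3)
    degenerate_faces: np.ndarray    # (k,) int indices
    bad_vertices: np.ndarray        # (m,) int indices


def face_normals(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit normals and areas per face.

    Normal = normalized (p1-p0) x (p2-p0); orientation follows the face
    winding.  Area = half the cross-product magnitude.

    Returns
    -------
    normals : (F, 3) array, zero rows for degenerate faces
    areas : (F,) array
    degenerate : (k,) int array of degenerate face indices
    """
    tri = mesh.face_coordinates()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(cross, axis=1)
    degenerate = np.flatnonzero(norm < DEGENERATE_AREA_EPSILON)
    if degenerate.size:
        warnings.warn(
            f"{mesh.name or 'mesh'}: {degenerate.size} degenerate face(s) excluded",
            stacklevel=2,
        )
    normals = np.zeros_like(cross)
    ok = norm >= DEGENERATE_AREA_EPSILON
    normals[ok] = cross[ok] / norm[ok, None]
    return normals, norm / 2.0, degenerate


def vertex_normals(mesh: TriangleMesh, f_normals: np.ndarray,
                   degenerate: np.ndarray | None = None,
                   area_weighted: bool = False,
                   f_areas: np.ndarray | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex unit normals as the normalized average of incident face
    normals.

    The average is unweighted by default; ``area_weighted=True`` weights by
    face area instead (requires ``f_areas``).  Degenerate faces do not
    contribute.  Vertices whose averaged normal has near-zero length are
    returned in ``bad_vertices`` with a zero normal.
    """
    V = mesh.vertex_count
    acc = np.zeros((V, 3))
    cnt = np.zeros(V)
    contrib = np.ones(mesh.face_count, dtype=bool)
    if degenerate is not None and len(degenerate):
        contrib[degenerate] = False
    if area_weighted:
        if f_areas is None:
            raise ValueError("area_weighted vertex normals require face areas")
        w = np.where(contrib, f_areas, 0.0)
    else:
        w = contrib.astype(np.float64)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], f_normals * w[:, None])
        np.add.at(cnt, mesh.faces[:, k], w)
    if np.any(cnt == 0):
        isolated = np.flatnonzero(cnt == 0)
        raise MeshError(
            f"{mesh.name or 'mesh'}: {isolated.size} vertex(es) with no "
            f"non-degenerate incident face (first: {isolated[0]})"
        )
    norms = np.linalg.norm(acc, axis=1)
    bad = np.flatnonzero(norms < 1e-12)
    out = np.zeros_like(acc)
    ok = norms >= 1e-12
    out[ok] = acc[ok] / norms[ok, None]
    return out, bad


def compute_normal_field(mesh: TriangleMesh, area_weighted: bool = False) -> NormalField:
    """Convenience wrapper bundling face and vertex normals."""
    fn, fa, degen = face_normals(mesh)
    vn, bad = vertex_normals(mesh, fn, degen, area_weighted=area_weighted, f_areas=fa)
    return NormalField(fn, fa, vn, degen, bad)


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyIndex:
    """Edge/face incidence for a triangle mesh.

    ``edge_to_faces`` maps each undirected edge (i, j) with i < j to the
    list of face indices containing it.  On a closed manifold every edge
    maps to exactly 2 faces.
    """

    edge_to_faces: dict
    face_neighbors: list            # per-face list of edge-sharing faces
    vertex_to_faces: list           # per-vertex list of incident faces

    @property
    def edge_count(self) -> int:
        return len(self.edge_to_faces)


def build_adjacency(mesh: TriangleMesh) -> AdjacencyIndex:
    """Build the edge->faces, face->neighbors, vertex->faces indices."""
    F = mesh.face_count
    edge_to_faces: dict = {}
    faces = mesh.faces
    for f in range(F):
        a, b, c = faces[f]
        for i, j in ((a, b), (b, c), (c, a)):
            key = (int(i), int(j)) if i < j else (int(j), int(i))
            edge_to_faces.setdefault(key, []).append(f)
    face_neighbors = [[] for _ in range(F)]
    for fs in edge_to_faces.values():
        for x in fs:
            for y in fs:
                if x != y:
                    face_neighbors[x].append(y)
    vertex_to_faces = [[] for _ in range(mesh.vertex_count)]
    for f in range(F):
        for v in faces[f]:
            vertex_to_faces[int(v)].append(f)
    return AdjacencyIndex(edge_to_faces, face_neighbors, vertex_to_faces)


def boundary_faces(mesh: TriangleMesh, adjacency: AdjacencyIndex) -> set[int]:
    """Faces owning at least one edge incident to only one face.

    These are the rim of a hole (e.g. the cropped cervical margin of a
    tooth crown); vertices there lack a full fan of incident faces, so
    their averaged normals — and hence DNE — are unreliable.  A closed
    mesh returns the empty set.
    """
    out: set[int] = set()
    for fs in adjacency.edge_to_faces.values():
        if len(fs) == 1:
            out.add(fs[0])
    return out


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Rotation about X, then Y, then Z (degrees), then translation."""

    rx_deg: float = 0.0
    ry_deg: float = 0.0
    rz_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """Composite rotation matrix Rz @ Ry @ Rx (X applied first)."""
        ax, ay, az = np.radians([self.rx_deg, self.ry_deg, self.rz_deg])
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def inverse(self) -> "RigidTransform":
        # inverse of a pure-rotation transform; translations compose
        # outside this helper
        return RigidTransform(-self.rx_deg, -self.ry_deg, -self.rz_deg)


def rotate_mesh(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Apply a rigid transform to the vertices; faces unchanged."""
    v = mesh.vertices @ transform.matrix().T + np.asarray(transform.translation)
    return TriangleMesh(v, mesh.faces.copy(), name=mesh.name)


def rotate_z(mesh: TriangleMesh, degrees: float) -> TriangleMesh:
    return rotate_mesh(mesh, RigidTransform(rz_deg=degrees))


def center_on_origin(mesh: TriangleMesh) -> TriangleMesh:
    """Translate so the vertex-coordinate centroid sits at the origin."""
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    return TriangleMesh(v, mesh.faces.copy(), name=mesh.name)


# ---------------------------------------------------------------------------
# implicit fairing
# ---------------------------------------------------------------------------

def _umbrella_laplacian(mesh: TriangleMesh) -> scipy.sparse.csr_matrix:
    """Uniform-weight (umbrella) graph Laplacian L = D^-1 A - I.

    Rows sum to zero; L @ X gives, per vertex, the mean of edge-connected
    neighbors minus the vertex itself.
    """
    e0 = mesh.faces[:, [0, 1, 2]].ravel()
    e1 = mesh.faces[:, [1, 2, 0]].ravel()
    i = np.concatenate([e0, e1])
    j = np.concatenate([e1, e0])
    V = mesh.vertex_count
    A = scipy.sparse.coo_matrix((np.ones(i.size), (i, j)), shape=(V, V)).tocsr()
    A.data[:] = 1.0  # duplicates were summed; restore 0/1 adjacency
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise MeshError("isolated vertex: umbrella Laplacian undefined")
    Dinv = scipy.sparse.diags(1.0 / deg)
    return (Dinv @ A - scipy.sparse.identity(V)).tocsr()


def implicit_fair_smooth(mesh: TriangleMesh, iterations: int,
                         lam: float = 0.6) -> TriangleMesh:
    """Implicit fairing: per iteration solve (I - lam*L) X' = X.

    Backward-Euler integration of Laplacian diffusion — unconditionally
    stable, so ``lam`` can be large (default 0.6, the conventional
    smoothing strength for scanned dental meshes).  Topology is unchanged;
    ``iterations=0`` is the identity.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mesh.copy()
    L = _umbrella_laplacian(mesh)
    V = mesh.vertex_count
    A = (scipy.sparse.identity(V) - lam * L).tocsc()
    solve = scipy.sparse.linalg.factorized(A)
    X = mesh.vertices.copy()
    for _ in range(iterations):
        rhs = X
        X = np.column_stack([solve(rhs[:, k]) for k in range(3)])
        resid = np.abs(A @ X - rhs).max()
        scale = max(np.abs(rhs).max(), 1.0)
        if not np.isfinite(resid) or resid > 1e-6 * scale:
            raise ArithmeticError(
                f"implicit fairing solve did not converge (residual {resid:.3e})"
            )
    return TriangleMesh(X, mesh.faces.copy(), name=mesh.name)
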