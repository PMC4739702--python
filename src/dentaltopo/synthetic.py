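"""Deterministic synthetic meshes with known analytic properties.

Real molar scans are large binary assets; these generators produce
fixtures whose area, curvature, boundary, and patch structure are known
in closed form, so every metric can be verified against an analytic or
brute-force oracle:

* ``make_plane`` — flat or tilted grid: DNE 0, RFI 1, OPC 0 (flat) / 1
  (tilted).
* ``make_icosphere`` — closed sphere: DNE -> 8*pi*, OPC = 8, no boundary.
* ``make_hemisphere`` — open dome: RFI -> 2, one boundary rim.
* ``make_gaussian_cusps`` — tooth-like heightfield of Gaussian cusps with
  an analytic gradient, optionally with seeded vertex noise along
  normals (emulating scanner noise for the smoothing/outlier options).

The same spec and seed always reproduce a bit-identical mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh.creation

from .mesh import TriangleMesh
from . import ops


@dataclass
class FixtureSpec:
    """Declarative description of a Gaussian-cusp fixture.

    ``cusps`` holds ((cx, cy), height, sigma) triples with centers inside
    the unit domain; ``noise_sigma`` is the standard deviation of seeded
    Gaussian displacement applied along vertex normals, in mesh units.
    """

    grid: tuple[int, int] = (60, 60)
    cusps: tuple = ()
    noise_sigma: float = 0.0
    seed: int = 0


def make_plane(nx: int, ny: int, tilt_deg: float = 0.0) -> TriangleMesh:
    """Regular triangulated grid on [0,1]^2, rotated tilt_deg about X.

    2*(nx-1)*(ny-1) faces.  A 0-degree tilt gives the flat occlusal-plane
    reference (area 1, DNE 0, all normals +Z).
    """
    if nx < 2 or ny < 2:
        raise ValueError("grid counts must be >= 2")
    x = np.linspace(0.0, 1.0, nx)
    y = np.linspace(0.0, 1.0, ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(nx * ny)])
    faces = _grid_faces(nx, ny)
    mesh = TriangleMesh(vertices, faces, name=f"plane_{nx}x{ny}")
    if tilt_deg:
        mesh = ops.rotate_mesh(mesh, ops.RigidTransform(rx_deg=tilt_deg))
    return mesh


def _grid_faces(nx: int, ny: int) -> np.ndarray:
    """Two consistently wound triangles per grid cell (normals +Z)."""
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (i * ny + j).ravel()
    v01 = (i * ny + j + 1).ravel()
    v10 = ((i + 1) * ny + j).ravel()
    v11 = ((i + 1) * ny + j + 1).ravel()
    # CCW seen from +Z: (v00, v10, v11) and (v00, v11, v01)
    return np.concatenate([
        np.column_stack([v00, v10, v11]),
        np.column_stack([v00, v11, v01]),
    ]).astype(np.int64)


def make_icosphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    """Closed icosphere: 20*4^s faces, 10*4^s+2 vertices, outward winding."""
    if not (0 <= subdivisions <= 6):
        raise ValueError("subdivisions must be in 0..6")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                        name=f"icosphere_s{subdivisions}")


def make_hemisphere(subdivisions: int, radius: float = 1.0) -> TriangleMesh:
    """Open upper hemisphere (dome up): icosphere faces with all-corner
    z >= -eps retained, unused vertices dropped, single boundary rim."""
    sphere = make_icosphere(subdivisions, radius)
    eps = 1e-9 * radius
    keep = np.all(sphere.vertices[sphere.faces][:, :, 2] >= -eps, axis=1)
    faces = sphere.faces[keep]
    used = np.unique(faces)
    remap = np.full(sphere.vertex_count, -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return TriangleMesh(sphere.vertices[used], remap[faces],
                        name=f"hemisphere_s{subdivisions}")


def cusp_height(spec: FixtureSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic heightfield h(x, y) of the Gaussian-cusp fixture."""
    h = np.zeros_like(np.asarray(x, dtype=np.float64))
    for (cx, cy), height, sigma in spec.cusps:
        h = h + height * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma ** 2))
    return h


def cusp_gradient(spec: FixtureSpec, x: np.ndarray, y: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (dh/dx, dh/dy), for quadrature oracles of 3D area."""
    gx = np.zeros_like(np.asarray(x, dtype=np.float64))
    gy = np.zeros_like(gx)
    for (cx, cy), height, sigma in spec.cusps:
        g = height * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma ** 2))
        gx = gx - g * (x - cx) / sigma ** 2
        gy = gy - g * (y - cy) / sigma ** 2
    return gx, gy


def make_gaussian_cusps(spec: FixtureSpec) -> TriangleMesh:
    """Triangulated Gaussian-cusp heightfield on [0,1]^2.

    Optional seeded Gaussian noise is displaced along vertex normals,
    mimicking scanner noise.  Same spec + seed -> bit-identical mesh.
    """
    nx, ny = spec.grid
    if nx < 50 or ny < 50:
        raise ValueError("cusp fixture grid must be >= 50x50")
    for (cx, cy), _, _ in spec.cusps:
        if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
            raise ValueError(f"cusp center ({cx}, {cy}) outside the unit domain")
    x = np.linspace(0.0, 1.0, nx)
    y = np.linspace(0.0, 1.0, ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    zz = cusp_height(spec, xx, yy)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    mesh = TriangleMesh(vertices, _grid_faces(nx, ny),
                        name=f"cusps_{len(spec.cusps)}")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        fn, fa, degen = ops.face_normals(mesh)
        vn, _ = ops.vertex_normals(mesh, fn, degen)
        disp = rng.normal(0.0, spec.noise_sigma, size=mesh.vertex_count)
        mesh = TriangleMesh(mesh.vertices + disp[:, None] * vn, mesh.faces,
                            name=mesh.name + "_noisy")
    return mesh
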