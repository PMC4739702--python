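"""Relief index (RFI): 3D surface area over projected 2D outline area.

RFI = 3da / 2da, where 3da is the summed triangle area of the mesh and
2da is the area of its silhouette projected onto the XY (occlusal) plane.
The mesh must already be oriented with the occlusal plane parallel to XY
— this package deliberately does not auto-orient (relief is sensitive to
orientation; use the ``meshrotate`` CLI subcommand to orient explicitly).

2da is measured by rasterization, automating the classic workflow of
exporting an occlusal-view bitmap and counting pixels against a scale
bar: project every face onto XY, fill each pixel whose center falls
inside any projected triangle (stacked regions — undercuts — fill a pixel
once), and multiply the filled count by the pixel area.  Discretization
error is O(silhouette perimeter x pixel size), so the estimate converges
as resolution grows.

Both published report forms are always emitted alongside the plain
ratio: RFI x 100 and ln(RFI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh
from . import ops


@dataclass
class RFIResult:
    area_3d: float          # 3da, squared mesh units
    area_2d: float          # 2da, squared mesh units
    rfi_ratio: float        # 3da / 2da
    rfi_x100: float         # 100 * ratio
    rfi_ln: float           # ln(ratio)
    raster_resolution: int  # pixels along the longest XY extent


def surface_area_3d(mesh: TriangleMesh) -> float:
    """Total mesh surface area (sum of triangle areas)."""
    _, areas, _ = ops.face_normals(mesh)
    return float(areas.sum())


def projected_area_2d(mesh: TriangleMesh, resolution: int = 1000) -> float:
    """Rasterized area of the mesh's XY silhouette.

    ``resolution`` pixels span the longest side of the XY bounding box
    (minimum 100).  A pixel counts if its center lies inside (or exactly
    on the edge of) any projected triangle; overlap fills once.
    """
    if resolution < 100:
        raise ValueError("raster resolution must be >= 100 pixels")
    mesh.validate()
    xy = mesh.vertices[:, :2]
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    extent = hi - lo
    longest = float(extent.max())
    if longest <= 0:
        raise ValueError("degenerate projection: mesh has zero XY extent")
    px = longest / resolution
    nx = max(int(np.ceil(extent[0] / px)), 1)
    ny = max(int(np.ceil(extent[1] / px)), 1)

    filled = np.zeros((ny, nx), dtype=bool)
    tri = xy[mesh.faces]  # (F, 3, 2)
    # per-face signed doubled area; skip projections that collapse to a line
    d = ((tri[:, 1, 0] - tri[:, 0, 0]) * (tri[:, 2, 1] - tri[:, 0, 1])
         - (tri[:, 2, 0] - tri[:, 0, 0]) * (tri[:, 1, 1] - tri[:, 0, 1]))
    xs = lo[0] + (np.arange(nx) + 0.5) * px
    ys = lo[1] + (np.arange(ny) + 0.5) * px
    for f in np.flatnonzero(np.abs(d) > 1e-300):
        t = tri[f]
        i0 = np.searchsorted(xs, t[:, 0].min() - px)
        i1 = np.searchsorted(xs, t[:, 0].max() + px)
        j0 = np.searchsorted(ys, t[:, 1].min() - px)
        j1 = np.searchsorted(ys, t[:, 1].max() + px)
        if i0 >= i1 or j0 >= j1:
            continue
        gx = xs[i0:i1][None, :]
        gy = ys[j0:j1][:, None]
        sign = 1.0 if d[f] > 0 else -1.0
        inside = np.ones((j1 - j0, i1 - i0), dtype=bool)
        for a, b in ((0, 1), (1, 2), (2, 0)):
            cross = ((t[b, 0] - t[a, 0]) * (gy - t[a, 1])
                     - (gx - t[a, 0]) * (t[b, 1] - t[a, 1]))
            inside &= sign * cross >= 0
        filled[j0:j1, i0:i1] |= inside
    return float(filled.sum()) * px * px


def compute_rfi(mesh: TriangleMesh, resolution: int = 1000) -> RFIResult:
    """Relief index with both published report forms.

    Stacked surface (undercuts) counts fully toward 3da but once toward
    2da, so RFI of any surface covering its own silhouette is >= 1 up to
    raster error.
    """
    a3 = surface_area_3d(mesh)
    a2 = projected_area_2d(mesh, resolution)
    if a2 <= 0:
        raise ValueError("projected area is zero; cannot form relief index")
    ratio = a3 / a2
    return RFIResult(a3, a2, ratio, 100.0 * ratio, float(np.log(ratio)), resolution)
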