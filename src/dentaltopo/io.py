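"""Mesh and results file I/O.

Reads and writes ASCII Stanford PLY (the analysis input format), converts
binary PLY to ASCII, exports OFF, and writes the batch-results TSV.

Conventions
-----------
* Face indices are 0-based both internally and in PLY/OFF files (the PLY
  and OFF standards are 0-based).  GIS-derived tools are often 1-based;
  check before mixing exports.
* Vertex properties beyond x, y, z (normals, colors) are skipped on read
  and never stored: normals are always recomputed from geometry.
* ASCII output carries 6 significant digits per coordinate, which exceeds
  surface-scanner precision while keeping files diff-able.
* Faces declared with more than 3 vertices are rejected, not fan
  triangulated: every metric here assumes triangles, and silent
  re-triangulation would change DNE and OPCR values.
"""

from __future__ import annotations

import dataclasses
import math
import struct
from pathlib import Path
from typing import Sequence

import numpy as np

from .mesh import MeshError, TriangleMesh


class PlyError(ValueError):
    """Malformed PLY content (header or payload)."""


class BinaryPlyError(PlyError):
    """ASCII reader hit a binary-encoded PLY.

    Binary meshes (e.g. Geomagic exports) must first be converted with
    :func:`convert_binary_to_ascii`.
    """


_SCALAR_TYPES = {
    "char": ("b", 1), "int8": ("b", 1),
    "uchar": ("B", 1), "uint8": ("B", 1),
    "short": ("h", 2), "int16": ("h", 2),
    "ushort": ("H", 2), "uint16": ("H", 2),
    "int": ("i", 4), "int32": ("i", 4),
    "uint": ("I", 4), "uint32": ("I", 4),
    "float": ("f", 4), "float32": ("f", 4),
    "double": ("d", 8), "float64": ("d", 8),
}


@dataclasses.dataclass
class _PlyHeader:
    fmt: str                      # 'ascii', 'binary_little_endian', 'binary_big_endian'
    elements: list                # [(name, count, [property descriptors])]
    body_offset: int              # byte offset of first payload byte

    def element(self, name):
        for el in self.elements:
            if el[0] == name:
                return el
        return None


def _parse_header(raw: bytes):
    """Parse a PLY header from raw bytes, returning a _PlyHeader.

    Property descriptors are ('list', count_type, item_type, name) or
    ('scalar', type, name).
    """
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise PlyError("not a PLY file: missing 'ply' magic or 'end_header'")
    nl = raw.find(b"\n", end)
    if nl < 0:
        raise PlyError("header not terminated by newline after end_header")
    header_text = raw[:nl].decode("ascii", errors="replace")
    body_offset = nl + 1

    fmt = None
    elements: list = []
    for lineno, line in enumerate(header_text.splitlines(), start=1):
        tokens = line.split()
        if not tokens or tokens[0] in ("ply", "comment", "obj_info", "end_header"):
            continue
        kw = tokens[0]
        if kw == "format":
            if len(tokens) < 2:
                raise PlyError(f"line {lineno}: malformed format line")
            fmt = tokens[1]
        elif kw == "element":
            if len(tokens) != 3:
                raise PlyError(f"line {lineno}: malformed element line: {line!r}")
            try:
                count = int(tokens[2])
            except ValueError:
                raise PlyError(f"line {lineno}: element count not an integer: {line!r}")
            elements.append((tokens[1], count, []))
        elif kw == "property":
            if not elements:
                raise PlyError(f"line {lineno}: property before any element")
            if tokens[1] == "list":
                if len(tokens) != 5:
                    raise PlyError(f"line {lineno}: malformed list property: {line!r}")
                elements[-1][2].append(("list", tokens[2], tokens[3], tokens[4]))
            else:
                if len(tokens) != 3:
                    raise PlyError(f"line {lineno}: malformed property: {line!r}")
                elements[-1][2].append(("scalar", tokens[1], tokens[2]))
        else:
            raise PlyError(f"line {lineno}: unknown header keyword {kw!r}")
    if fmt is None:
        raise PlyError("header missing 'format' line")
    if fmt not in ("ascii", "binary_little_endian", "binary_big_endian"):
        raise PlyError(f"unsupported PLY format {fmt!r}")
    return _PlyHeader(fmt, elements, body_offset)


def _read_raw(source) -> tuple[bytes, str]:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            data = data.encode("utf-8")
        return data, getattr(source, "name", "<stream>")
    path = Path(source)
    return path.read_bytes(), path.stem


def read_ply(source) -> TriangleMesh:
    """Read an ASCII Stanford PLY file into a :class:`TriangleMesh`.

    Parameters
    ----------
    source : path or readable stream
        ASCII PLY with a ``vertex`` element whose first three numeric
        properties are x, y, z, and a ``face`` element of triangular
        vertex-index lists.  Extra vertex properties (normals, colors)
        are tolerated and ignored.

    Raises
    ------
    BinaryPlyError
        For binary-encoded PLY; convert with
        :func:`convert_binary_to_ascii` first.
    PlyError
        For malformed headers, count mismatches, or non-triangular faces.
    """
    raw, name = _read_raw(source)
    header = _parse_header(raw)
    if header.fmt != "ascii":
        raise BinaryPlyError(
            f"{name}: binary encoding ({header.fmt}); convert to ASCII first "
            "with convert_binary_to_ascii()"
        )
    vert_el = header.element("vertex")
    face_el = header.element("face")
    if vert_el is None or face_el is None:
        raise PlyError(f"{name}: PLY must declare 'vertex' and 'face' elements")

    body = raw[header.body_offset:].decode("ascii", errors="replace")
    lines = [ln for ln in body.splitlines() if ln.strip()]
    # payload rows are consumed in header element order
    cursor = 0
    vertices = faces = None
    for el_name, count, props in header.elements:
        rows = lines[cursor:cursor + count]
        if len(rows) < count:
            raise PlyError(
                f"{name}: element '{el_name}' declares {count} rows, "
                f"found {len(rows)} (payload row {cursor + len(rows) + 1})"
            )
        cursor += count
        if el_name == "vertex":
            if len(props) < 3:
                raise PlyError(f"{name}: vertex element declares fewer than 3 properties")
            vertices = np.empty((count, 3), dtype=np.float64)
            for i, row in enumerate(rows):
                parts = row.split()
                if len(parts) < 3:
                    raise PlyError(f"{name}: vertex row {i + 1} too short: {row!r}")
                try:
                    vertices[i] = [float(parts[0]), float(parts[1]), float(parts[2])]
                except ValueError:
                    raise PlyError(f"{name}: vertex row {i + 1} not numeric: {row!r}")
        elif el_name == "face":
            faces = np.empty((count, 3), dtype=np.int64)
            for i, row in enumerate(rows):
                parts = row.split()
                try:
                    n = int(parts[0])
                except (ValueError, IndexError):
                    raise PlyError(f"{name}: face row {i + 1} malformed: {row!r}")
                if n != 3:
                    raise PlyError(
                        f"{name}: non-triangular face ({n} vertices) at face row "
                        f"{i + 1}; triangulate the mesh before analysis"
                    )
                if len(parts) < 4:
                    raise PlyError(f"{name}: face row {i + 1} truncated: {row!r}")
                faces[i] = [int(parts[1]), int(parts[2]), int(parts[3])]
    if vertices is None or faces is None:
        raise PlyError(f"{name}: missing vertex or face payload")
    return TriangleMesh(vertices, faces, name=name).validate()


def write_ply(mesh: TriangleMesh, dest) -> None:
    """Write a mesh as ASCII Stanford PLY (6 significant digits)."""
    mesh.validate()
    lines = [
        "ply",
        "format ascii 1.0",
        "comment produced by dentaltopo",
        f"element vertex {mesh.vertex_count}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {mesh.face_count}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def write_off(mesh: TriangleMesh, dest) -> None:
    """Write a mesh in OFF format ('OFF' magic, 'V F E' counts, E = 0)."""
    mesh.validate()
    lines = ["OFF", f"{mesh.vertex_count} {mesh.face_count} 0"]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def _decode_binary_body(raw: bytes, header: _PlyHeader, name: str):
    """Sequentially decode a binary PLY payload; returns vertices, faces."""
    endian = "<" if header.fmt == "binary_little_endian" else ">"
    offset = header.body_offset
    vertices = faces = None
    for el_name, count, props in header.elements:
        has_list = any(p[0] == "list" for p in props)
        if not has_list:
            # fixed-stride element: decode the x,y,z columns in one pass
            codes, names = [], []
            for p in props:
                if p[1] not in _SCALAR_TYPES:
                    raise PlyError(f"{name}: unsupported property type {p[1]!r} in '{el_name}'")
                codes.append(_SCALAR_TYPES[p[1]][0])
                names.append(p[2])
            fmt = endian + "".join(codes)
            stride = struct.calcsize(fmt)
            end = offset + stride * count
            if end > len(raw):
                raise PlyError(f"{name}: truncated binary payload in element '{el_name}'")
            rows = list(struct.iter_unpack(fmt, raw[offset:end]))
            offset = end
            if el_name == "vertex":
                if len(names) < 3:
                    raise PlyError(f"{name}: vertex element has fewer than 3 properties")
                arr = np.array(rows, dtype=np.float64)
                vertices = arr[:, :3]
        else:
            out = []
            for i in range(count):
                row_lists = []
                for p in props:
                    if p[0] == "list":
                        _, ctype, itype, _pname = p
                        if ctype not in _SCALAR_TYPES or itype not in _SCALAR_TYPES:
                            raise PlyError(f"{name}: unsupported list types {ctype!r}/{itype!r}")
                        ccode, csize = _SCALAR_TYPES[ctype]
                        icode, isize = _SCALAR_TYPES[itype]
                        if offset + csize > len(raw):
                            raise PlyError(f"{name}: truncated binary payload (row {i + 1} of '{el_name}')")
                        (n,) = struct.unpack_from(endian + ccode, raw, offset)
                        offset += csize
                        if offset + n * isize > len(raw):
                            raise PlyError(f"{name}: truncated binary payload (row {i + 1} of '{el_name}')")
                        items = struct.unpack_from(endian + str(n) + icode, raw, offset)
                        offset += n * isize
                        row_lists.append(items)
                    else:
                        _, stype, _pname = p
                        if stype not in _SCALAR_TYPES:
                            raise PlyError(f"{name}: unsupported property type {stype!r}")
                        scode, ssize = _SCALAR_TYPES[stype]
                        if offset + ssize > len(raw):
                            raise PlyError(f"{name}: truncated binary payload (row {i + 1} of '{el_name}')")
                        struct.unpack_from(endian + scode, raw, offset)
                        offset += ssize
                out.append(row_lists[0] if row_lists else ())
            if el_name == "face":
                for i, idx in enumerate(out):
                    if len(idx) != 3:
                        raise PlyError(
                            f"{name}: non-triangular face ({len(idx)} vertices) at row {i + 1}"
                        )
                faces = np.array(out, dtype=np.int64)
    if vertices is None or faces is None:
        raise PlyError(f"{name}: binary PLY missing vertex or face element")
    return vertices, faces


def convert_binary_to_ascii(source, dest) -> TriangleMesh:
    """Convert a binary-encoded PLY file to ASCII encoding.

    Decodes little- or big-endian payloads with float x,y,z vertex
    properties and uchar-count integer face index lists, then writes the
    mesh via :func:`write_ply`.  Returns the decoded mesh.

    Raises
    ------
    PlyError
        If the source is already ASCII, uses unsupported property types,
        or is truncated mid-payload.
    """
    raw, name = _read_raw(source)
    header = _parse_header(raw)
    if header.fmt == "ascii":
        raise PlyError(f"{name}: already ASCII encoded; no conversion needed")
    vertices, faces = _decode_binary_body(raw, header, name)
    mesh = TriangleMesh(vertices, faces, name=name).validate()
    write_ply(mesh, dest)
    return mesh


# ---------------------------------------------------------------------------
# batch results
# ---------------------------------------------------------------------------

TSV_COLUMNS = (
    "Specimen", "DNE", "RFI", "3DArea", "2DArea", "OPCR",
    "OPC_r0", "OPC_r1", "OPC_r2", "OPC_r3",
    "OPC_r4", "OPC_r5", "OPC_r6", "OPC_r7",
)


@dataclasses.dataclass
class ResultRecord:
    """One specimen's metric results; absent metrics stay ``None``.

    ``opcr`` must equal the mean of ``opc_per_rotation`` when both are
    present, and ``rfi`` must equal ``area_3d / area_2d`` when all three
    are present (checked to 1e-9 by :meth:`check`).
    """

    specimen_name: str
    dne: float | None = None
    rfi: float | None = None
    area_3d: float | None = None
    area_2d: float | None = None
    opcr: float | None = None
    opc_per_rotation: Sequence[int] | None = None

    def check(self) -> "ResultRecord":
        if self.opcr is not None and self.opc_per_rotation is not None:
            if not math.isclose(self.opcr, float(np.mean(self.opc_per_rotation)),
                                rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"{self.specimen_name}: OPCR != mean of per-rotation OPC")
        if self.rfi is not None and self.area_3d is not None and self.area_2d is not None:
            if not math.isclose(self.rfi, self.area_3d / self.area_2d,
                                rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(f"{self.specimen_name}: RFI != 3DArea/2DArea")
        return self


def _fmt(x) -> str:
    return "NA" if x is None else (f"{x:.6f}" if isinstance(x, float) else str(x))


def write_results_tsv(records: Sequence[ResultRecord], dest,
                      header_comments: Sequence[str] = ()) -> None:
    """Write batch results as TSV: one header row plus one row per record.

    ``header_comments`` lines (run provenance: options in effect) are
    prefixed with '# ' above the header.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record list: nothing to write")
    lines = [f"# {c}" for c in header_comments]
    lines.append("\t".join(TSV_COLUMNS))
    for r in records:
        r.check()
        opc = list(r.opc_per_rotation) if r.opc_per_rotation is not None else [None] * 8
        if len(opc) != 8:
            raise ValueError(f"{r.specimen_name}: expected 8 per-rotation OPC values")
        row = [r.specimen_name, _fmt(r.dne), _fmt(r.rfi), _fmt(r.area_3d),
               _fmt(r.area_2d), _fmt(r.opcr)] + [_fmt(v) for v in opc]
        lines.append("\t".join(row))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
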