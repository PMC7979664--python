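"""VTK unstructured-grid I/O for tetrahedral cell meshes.

Supports the legacy ASCII format (``.vtk``) and the XML format (``.vtu``,
ASCII-encoded), restricted to tetrahedral cells (VTK cell type 10).
Coordinates are written with 17 significant digits so that a write/read
round-trip reproduces the float64 values bit-exactly.  The nominal cell
radius travels as field data (legacy) / mesh-level metadata (XML); optional
per-vertex vector fields (displacements, forces) can be written as point
data for visualization.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

import numpy as np

from .mesh import MeshError, TetMesh, surface_from_tets

__all__ = ["read_mesh", "write_mesh"]

VTK_TET = 10


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_mesh(mesh: TetMesh, path: str | os.PathLike,
               point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a tet mesh as VTK unstructured grid (.vtk legacy ASCII or .vtu).

    ``point_data`` maps field names to (n_vertices, 3) vector arrays.
    """
    path = os.fspath(path)
    if path.endswith(".vtu"):
        _write_vtu(mesh, path, point_data)
    else:
        _write_legacy(mesh, path, point_data)


def read_mesh(path: str | os.PathLike) -> TetMesh:
    """Read a tetrahedral VTK unstructured grid (.vtk legacy ASCII or .vtu).

    Surface triangles are re-derived from the connectivity.  Raises
    :class:`MeshError` for non-tetrahedral cells or empty meshes, and
    ``FileNotFoundError`` for a missing file.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".vtu"):
        vertices, tets, radius = _read_vtu(path)
    else:
        vertices, tets, radius = _read_legacy(path)
    if len(tets) == 0 or len(vertices) == 0:
        raise MeshError(f"empty mesh in {path}")
    if radius is None:
        c = vertices.mean(axis=0)
        radius = float(np.linalg.norm(vertices - c, axis=1).max())
    tris = surface_from_tets(vertices, tets)
    return TetMesh(vertices=vertices, tets=tets, surface_tris=tris, radius=radius)


def _write_legacy(mesh, path, point_data):
    n_v, n_t = mesh.n_vertices, mesh.n_tets
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhypercell tetrahedral mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write("FIELD FieldData 1\nradius 1 1 double\n")
        fh.write(_fmt(mesh.radius) + "\n")
        fh.write(f"POINTS {n_v} double\n")
        for p in mesh.vertices:
            fh.write(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        fh.write(f"CELLS {n_t} {5 * n_t}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {n_t}\n")
        fh.write("\n".join([str(VTK_TET)] * n_t) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {n_v}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=np.float64).reshape(n_v, 3)
                fh.write(f"VECTORS {name} double\n")
                for v in arr:
                    fh.write(f"{_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}\n")


def _read_legacy(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    radius = None
    i = 0
    vertices = tets = None
    while i < len(lines):
        line = lines[i].strip()
        up = line.upper()
        if up.startswith("FIELD"):
            # next: "<name> 1 1 double" then the value
            name = lines[i + 1].split()[0]
            if name == "radius":
                radius = float(lines[i + 2].split()[0])
            i += 3
            continue
        if up.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            vertices = np.array(vals, dtype=np.float64).reshape(n, 3)
            continue
        if up.startswith("CELLS"):
            n = int(line.split()[1])
            cells = []
            i += 1
            for _ in range(n):
                parts = [int(v) for v in lines[i].split()]
                if parts[0] != 4:
                    raise MeshError(
                        f"non-tetrahedral cell with {parts[0]} vertices in {path}")
                cells.append(parts[1:5])
                i += 1
            tets = np.array(cells, dtype=np.int64)
            continue
        if up.startswith("CELL_TYPES"):
            n = int(line.split()[1])
            types = []
            i += 1
            while len(types) < n:
                types.extend(int(v) for v in lines[i].split())
                i += 1
            if any(t != VTK_TET for t in types):
                raise MeshError(f"non-tetrahedral cell type in {path}")
            continue
        i += 1
    if vertices is None or tets is None:
        raise MeshError(f"no unstructured grid found in {path}")
    return vertices, tets, radius


def _write_vtu(mesh, path, point_data):
    n_v, n_t = mesh.n_vertices, mesh.n_tets
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    grid.set("Radius", _fmt(mesh.radius))
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n_v),
                          NumberOfCells=str(n_t))
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64",
                       NumberOfComponents="3", format="ascii")
    da.text = "\n" + "\n".join(
        f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}" for p in mesh.vertices) + "\n"
    cells = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(cells, "DataArray", type="Int64", Name="connectivity",
                         format="ascii")
    conn.text = "\n" + "\n".join(
        f"{t[0]} {t[1]} {t[2]} {t[3]}" for t in mesh.tets) + "\n"
    offs = ET.SubElement(cells, "DataArray", type="Int64", Name="offsets",
                         format="ascii")
    offs.text = "\n" + "\n".join(str(4 * (i + 1)) for i in range(n_t)) + "\n"
    typ = ET.SubElement(cells, "DataArray", type="UInt8", Name="types",
                        format="ascii")
    typ.text = "\n" + "\n".join([str(VTK_TET)] * n_t) + "\n"
    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=np.float64).reshape(n_v, 3)
            d = ET.SubElement(pd, "DataArray", type="Float64", Name=name,
                              NumberOfComponents="3", format="ascii")
            d.text = "\n" + "\n".join(
                f"{_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}" for v in arr) + "\n"
    ET.ElementTree(root).write(path, xml_declaration=True)


def _read_vtu(path):
    root = ET.parse(path).getroot()
    grid = root.find("UnstructuredGrid")
    if grid is None:
        raise MeshError(f"not an unstructured grid: {path}")
    radius = float(grid.get("Radius")) if grid.get("Radius") else None
    piece = grid.find("Piece")
    if piece is None:
        raise MeshError(f"empty mesh in {path}")
    pts = piece.find("Points/DataArray")
    vertices = np.array((pts.text or "").split(), dtype=np.float64).reshape(-1, 3)
    arrays = {d.get("Name"): d for d in piece.findall("Cells/DataArray")}
    types = np.array((arrays["types"].text or "").split(), dtype=np.int64)
    if len(types) and not (types == VTK_TET).all():
        raise MeshError(f"non-tetrahedral cell type in {path}")
    offsets = np.array((arrays["offsets"].text or "").split(), dtype=np.int64)
    if len(offsets) and not (np.diff(np.r_[0, offsets]) == 4).all():
        raise MeshError(f"non-tetrahedral cell in {path}")
    conn = np.array((arrays["connectivity"].text or "").split(), dtype=np.int64)
    tets = conn.reshape(-1, 4)
    return vertices, tets, radius
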