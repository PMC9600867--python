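"""Mesh and field I/O: ASCII VTU (VTK unstructured grid), STL, CSV, JSON.

The VTU files written here use XML ASCII encoding with quadratic-triangle
cells (VTK type 22), a ``tissue_label`` integer cell field and optional
point/cell data arrays.  Floats are printed with %.17g so a write/read
round-trip reproduces coordinates, connectivity and fields exactly.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .geometry import LabeledMesh

__all__ = ["write_vtu", "read_vtu", "write_boundary_stl", "write_report_json"]

VTK_QUADRATIC_TRIANGLE = 22
VTK_QUADRATIC_EDGE = 21


def _fmt_floats(arr):
    return "\n".join(" ".join(f"{v:.17g}" for v in row) for row in np.atleast_2d(arr))


def _fmt_ints(arr):
    return "\n".join(" ".join(str(int(v)) for v in np.atleast_1d(row)) for row in np.atleast_2d(arr))


def write_vtu(mesh: LabeledMesh, path, point_data=None, cell_data=None):
    """Write a labeled mesh (+ optional fields) as an ASCII .vtu file.

    Boundary tags are preserved as field data so :func:`read_vtu` can
    reconstruct the full :class:`LabeledMesh`.
    """
    path = Path(path)
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    cell_data.setdefault("tissue_label", mesh.element_labels)

    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    pts3 = np.column_stack([mesh.nodes, np.zeros(n_pts)])
    offsets = 6 * np.arange(1, n_cells + 1)
    types = np.full(n_cells, VTK_QUADRATIC_TRIANGLE)

    lines = []
    lines.append('<?xml version="1.0"?>')
    lines.append('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    lines.append("<UnstructuredGrid>")
    lines.append(f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">')
    lines.append("<Points>")
    lines.append('<DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    lines.append(_fmt_floats(pts3))
    lines.append("</DataArray>")
    lines.append("</Points>")
    lines.append("<Cells>")
    lines.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    lines.append(_fmt_ints(mesh.elements))
    lines.append("</DataArray>")
    lines.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    lines.append(_fmt_ints(offsets[None, :]))
    lines.append("</DataArray>")
    lines.append('<DataArray type="UInt8" Name="types" format="ascii">')
    lines.append(_fmt_ints(types[None, :]))
    lines.append("</DataArray>")
    lines.append("</Cells>")

    lines.append("<PointData>")
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        lines.append(
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">'
        )
        lines.append(_fmt_floats(arr))
        lines.append("</DataArray>")
    lines.append("</PointData>")

    lines.append("<CellData>")
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            lines.append(f'<DataArray type="Int64" Name="{name}" format="ascii">')
            lines.append(_fmt_ints(arr[None, :]))
        else:
            lines.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
            lines.append(_fmt_floats(arr[None, :]))
        lines.append("</DataArray>")
    lines.append("</CellData>")
    lines.append("</Piece>")
    lines.append("</UnstructuredGrid>")

    # boundary tags + metadata as an appended FieldData-like block
    meta = {
        "characteristic_h": mesh.characteristic_h,
        "lumen_center": list(mesh.lumen_center),
        "boundary_edges": {
            tag: np.asarray(edges).tolist()
            for tag, edges in mesh.boundary_edges.items()
        },
    }
    lines.append(f"<!--plaquestretch:{json.dumps(meta, sort_keys=True)}-->")
    lines.append("</VTKFile>")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtu(path):
    """Read a .vtu written by :func:`write_vtu`.

    Returns (mesh, point_data, cell_data); ``tissue_label`` is consumed into
    the mesh and also left in ``cell_data``.
    """
    path = Path(path)
    text = path.read_text()
    meta = {}
    marker = "<!--plaquestretch:"
    if marker in text:
        blob = text.split(marker, 1)[1].split("-->", 1)[0]
        meta = json.loads(blob)
        text = text.replace(marker + blob + "-->", "")
    root = ET.fromstring(text)
    piece = root.find(".//Piece")

    def parse(da, dtype):
        return np.array(da.text.split(), dtype=dtype)

    pts = None
    for da in piece.find("Points").iter("DataArray"):
        pts = parse(da, float).reshape(-1, 3)[:, :2]
    conn = offsets = types = None
    for da in piece.find("Cells").iter("DataArray"):
        name = da.get("Name")
        if name == "connectivity":
            conn = parse(da, np.int64)
        elif name == "offsets":
            offsets = parse(da, np.int64)
        elif name == "types":
            types = parse(da, np.int64)
    if not np.all(types == VTK_QUADRATIC_TRIANGLE):
        raise ValueError("expected a pure quadratic-triangle (VTK type 22) mesh")
    elements = conn.reshape(-1, 6)

    point_data = {}
    pd_node = piece.find("PointData")
    if pd_node is not None:
        for da in pd_node.iter("DataArray"):
            ncomp = int(da.get("NumberOfComponents", "1"))
            arr = parse(da, float)
            point_data[da.get("Name")] = arr.reshape(-1, ncomp) if ncomp > 1 else arr
    cell_data = {}
    cd_node = piece.find("CellData")
    if cd_node is not None:
        for da in cd_node.iter("DataArray"):
            dtype = np.int64 if da.get("type") == "Int64" else float
            cell_data[da.get("Name")] = parse(da, dtype)

    labels = cell_data.get("tissue_label")
    if labels is None:
        raise ValueError("mesh file lacks the tissue_label cell field")
    boundary = {
        tag: np.asarray(e, dtype=np.int64)
        for tag, e in meta.get("boundary_edges", {}).items()
    }
    mesh = LabeledMesh(
        nodes=pts,
        elements=elements,
        element_labels=np.asarray(labels, dtype=np.int64),
        boundary_edges=boundary,
        characteristic_h=float(meta.get("characteristic_h", np.nan)),
        lumen_center=tuple(meta.get("lumen_center", (0.0, 0.0))),
    )
    return mesh, point_data, cell_data


def write_boundary_stl(mesh: LabeledMesh, path, depth_mm: float = 1.0):
    """Export boundary loops as an ASCII STL ribbon of given axial depth.

    Each LUMEN/OUTER boundary edge becomes two triangles spanning z in
    [0, depth_mm] — a surface representation of the cross-section outline
    for interoperability with STL-based toolchains.
    """
    path = Path(path)
    lines = ["solid plaquestretch_boundaries"]

    def emit(p0, p1):
        a = np.array([*p0, 0.0])
        b = np.array([*p1, 0.0])
        a2 = a + [0, 0, depth_mm]
        b2 = b + [0, 0, depth_mm]
        for tri in ((a, b, b2), (a, b2, a2)):
            n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            nn = np.linalg.norm(n)
            n = n / nn if nn > 0 else n
            lines.append(f"facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}")
            lines.append("outer loop")
            for v in tri:
                lines.append(f"vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            lines.append("endloop")
            lines.append("endfacet")

    for tag in ("LUMEN", "OUTER"):
        for n0, n1, mid in mesh.boundary_edges[tag]:
            emit(mesh.nodes[n0], mesh.nodes[mid])
            emit(mesh.nodes[mid], mesh.nodes[n1])
    lines.append("endsolid plaquestretch_boundaries")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_report_json(report_dict: dict, path) -> Path:
    """Deterministic (sorted-keys) JSON report writer."""
    path = Path(path)
    path.write_text(json.dumps(report_dict, indent=2, sort_keys=True) + "\n")
    return path
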