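"""Read/write labelled tetrahedral meshes as ASCII VTU or Gmsh MSH 2.2.

VTU is the preferred interchange format: part and segment labels travel as
cell data (``part``, ``segment_id``), named node sets as 0/1 point-data
masks (``nodeset:<name>``), and optional result fields (e.g. ``von_mises``)
as additional cell data.  The MSH writer encodes the part as the physical
tag of each tetrahedron; node sets and segment ids do not survive an MSH
round trip, which is why VTU is preferred.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

import numpy as np

from .meshgen import TetMesh, PART_MUCOSA, PART_PLATE

__all__ = ["read_mesh", "write_mesh", "MeshFormatError"]

_VTK_TET = 10


class MeshFormatError(ValueError):
    """Raised when a mesh file is missing required structure or labels."""


def _fmt_array(a: np.ndarray, per_line: int) -> str:
    a = np.asarray(a)
    flat = a.ravel()
    if np.issubdtype(flat.dtype, np.integer):
        body = " ".join(str(int(v)) for v in flat)
    else:
        body = " ".join(repr(float(v)) for v in flat)
    return body


def write_mesh(mesh: TetMesh, path: str | os.PathLike, cell_data: dict | None = None) -> None:
    """Write a mesh to ``path``; format chosen by extension (.vtu or .msh)."""
    path = os.fspath(path)
    if path.endswith(".vtu"):
        _write_vtu(mesh, path, cell_data or {})
    elif path.endswith(".msh"):
        _write_msh(mesh, path)
    else:
        raise MeshFormatError(f"unsupported mesh extension: {path!r} (use .vtu or .msh)")


def read_mesh(path: str | os.PathLike) -> TetMesh:
    """Read a labelled tet mesh written by :func:`write_mesh`."""
    path = os.fspath(path)
    if path.endswith(".vtu"):
        return _read_vtu(path)
    if path.endswith(".msh"):
        return _read_msh(path)
    raise MeshFormatError(f"unsupported mesh extension: {path!r} (use .vtu or .msh)")


# ---------------------------------------------------------------- VTU


def _data_array(parent, name: str, a: np.ndarray, n_comp: int | None = None):
    a = np.asarray(a)
    if np.issubdtype(a.dtype, np.integer):
        vtk_type = "Int64"
    else:
        vtk_type = "Float64"
    el = ET.SubElement(parent, "DataArray", {"type": vtk_type, "Name": name, "format": "ascii"})
    if n_comp is not None and n_comp > 1:
        el.set("NumberOfComponents", str(n_comp))
    el.text = _fmt_array(a, 12)
    return el


def _write_vtu(mesh: TetMesh, path: str, extra_cell_data: dict) -> None:
    root = ET.Element(
        "VTKFile", {"type": "UnstructuredGrid", "version": "0.1", "byte_order": "LittleEndian"}
    )
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        grid,
        "Piece",
        {"NumberOfPoints": str(mesh.n_nodes), "NumberOfCells": str(mesh.n_tets)},
    )

    points = ET.SubElement(piece, "Points")
    _data_array(points, "Points", mesh.nodes, n_comp=3)

    cells = ET.SubElement(piece, "Cells")
    _data_array(cells, "connectivity", mesh.tets)
    _data_array(cells, "offsets", 4 * np.arange(1, mesh.n_tets + 1))
    _data_array(cells, "types", np.full(mesh.n_tets, _VTK_TET, dtype=np.int64))

    cdata = ET.SubElement(piece, "CellData")
    _data_array(cdata, "part", mesh.part)
    _data_array(cdata, "segment_id", mesh.segment_id)
    for name, values in extra_cell_data.items():
        _data_array(cdata, name, np.asarray(values))

    pdata = ET.SubElement(piece, "PointData")
    for name, idx in mesh.node_sets.items():
        mask = np.zeros(mesh.n_nodes, dtype=np.int64)
        mask[idx] = 1
        _data_array(pdata, f"nodeset:{name}", mask)

    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _parse_data_array(el) -> np.ndarray:
    text = el.text or ""
    if el.get("format", "ascii") != "ascii":
        raise MeshFormatError("only ascii VTU DataArrays are supported")
    tokens = text.split()
    if el.get("type", "").startswith("Int") or el.get("type", "").startswith("UInt"):
        return np.array(tokens, dtype=np.int64)
    return np.array(tokens, dtype=float)


def _read_vtu(path: str) -> TetMesh:
    tree = ET.parse(path)
    piece = tree.getroot().find("./UnstructuredGrid/Piece")
    if piece is None:
        raise MeshFormatError(f"{path}: not a VTU UnstructuredGrid file")

    arrays: dict[str, np.ndarray] = {}
    for section in ("Points", "Cells", "CellData", "PointData"):
        sec = piece.find(section)
        if sec is None:
            continue
        for el in sec.findall("DataArray"):
            arrays[f"{section}/{el.get('Name')}"] = _parse_data_array(el)

    try:
        nodes = arrays["Points/Points"].reshape(-1, 3)
        conn = arrays["Cells/connectivity"]
        types = arrays["Cells/types"]
    except KeyError as exc:
        raise MeshFormatError(f"{path}: missing required array {exc}") from exc
    if not np.all(types == _VTK_TET):
        raise MeshFormatError(f"{path}: only linear tetrahedral cells are supported")
    tets = conn.reshape(-1, 4)

    if "CellData/part" not in arrays:
        raise MeshFormatError(f"{path}: missing cell-data field 'part' (plate/mucosa labels)")
    part = arrays["CellData/part"].astype(np.int64)
    if not np.all(np.isin(part, (PART_MUCOSA, PART_PLATE))):
        raise MeshFormatError(f"{path}: 'part' labels must be 1 (mucosa) or 2 (plate)")
    segment_id = arrays.get(
        "CellData/segment_id", np.zeros(len(tets), dtype=np.int64)
    ).astype(np.int64)

    node_sets = {}
    for key, mask in arrays.items():
        if key.startswith("PointData/nodeset:"):
            node_sets[key.split("nodeset:", 1)[1]] = np.flatnonzero(mask)

    mesh = TetMesh(
        nodes=nodes, tets=tets, part=part, segment_id=segment_id, node_sets=node_sets
    )
    mesh.validate()
    return mesh


# ---------------------------------------------------------------- MSH (Gmsh 2.2)


def _write_msh(mesh: TetMesh, path: str) -> None:
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {float(x)!r} {float(y)!r} {float(z)!r}")
    lines += ["$EndNodes", "$Elements", str(mesh.n_tets)]
    for i, (tet, p) in enumerate(zip(mesh.tets, mesh.part), start=1):
        a, b, c, d = (int(v) + 1 for v in tet)
        lines.append(f"{i} 4 2 {int(p)} {int(p)} {a} {b} {c} {d}")
    lines += ["$EndElements", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _read_msh(path: str) -> TetMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        i_nodes = lines.index("$Nodes")
        i_elems = lines.index("$Elements")
    except ValueError as exc:
        raise MeshFormatError(f"{path}: missing $Nodes/$Elements section") from exc

    n_nodes = int(lines[i_nodes + 1])
    nodes = np.empty((n_nodes, 3))
    for row in lines[i_nodes + 2 : i_nodes + 2 + n_nodes]:
        tok = row.split()
        nodes[int(tok[0]) - 1] = [float(tok[1]), float(tok[2]), float(tok[3])]

    n_elems = int(lines[i_elems + 1])
    tets, part = [], []
    for row in lines[i_elems + 2 : i_elems + 2 + n_elems]:
        tok = row.split()
        etype, ntags = int(tok[1]), int(tok[2])
        if etype != 4:  # skip non-tet elements
            continue
        if ntags < 1:
            raise MeshFormatError(f"{path}: tetrahedron without a physical (part) tag")
        part.append(int(tok[3]))
        tets.append([int(v) - 1 for v in tok[3 + ntags : 7 + ntags]])
    if not tets:
        raise MeshFormatError(f"{path}: no tetrahedral elements found")
    part = np.asarray(part, dtype=np.int64)
    if not np.all(np.isin(part, (PART_MUCOSA, PART_PLATE))):
        raise MeshFormatError(f"{path}: physical tags must be 1 (mucosa) or 2 (plate)")
    mesh = TetMesh(
        nodes=nodes,
        tets=np.asarray(tets, dtype=np.int64),
        part=part,
        segment_id=np.zeros(len(tets), dtype=np.int64),
        node_sets={},
    )
    mesh.validate()
    return mesh
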