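"""Minimal ASCII VTK-XML unstructured-grid (.vtu) I/O for labeled meshes.

Writes tetrahedral meshes with the cell-data arrays ``tissue_class``
(int: 0 healthy, 1 BZ, 2 scar) and ``fiber`` (3-component float), plus any
extra point/cell arrays, in the plain-text VTK XML dialect readable by
ParaView and by :func:`read_vtu`.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import LabeledMesh

_VTK_TET = 10


def _fmt(arr: np.ndarray) -> str:
    if np.issubdtype(arr.dtype, np.integer):
        return " ".join(str(int(v)) for v in arr.ravel())
    return " ".join(format(float(v), ".17g") for v in arr.ravel())


def write_vtu(path, mesh: LabeledMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write a labeled mesh (plus optional extra data arrays) as ASCII .vtu."""
    cd = {"tissue_class": mesh.tissue_class.astype(np.int32), "fiber": mesh.fiber}
    if cell_data:
        cd.update(cell_data)
    pd = dict(point_data) if point_data else {}

    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "      <Points>",
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "          " + _fmt(mesh.nodes),
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
        "          " + _fmt(mesh.elements.astype(np.int64)),
        "        </DataArray>",
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + _fmt(np.arange(4, 4 * n_cells + 1, 4, dtype=np.int64)),
        "        </DataArray>",
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        "          " + _fmt(np.full(n_cells, _VTK_TET, dtype=np.uint8)),
        "        </DataArray>",
        "      </Cells>",
    ]

    def data_block(name: str, arrays: dict) -> list[str]:
        out = [f"      <{name}>"]
        for key, arr in arrays.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            vtype = "Int32" if np.issubdtype(arr.dtype, np.integer) else "Float64"
            out.append(
                f'        <DataArray type="{vtype}" Name="{key}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
            )
            out.append("          " + _fmt(arr))
            out.append("        </DataArray>")
        out.append(f"      </{name}>")
        return out

    if pd:
        lines += data_block("PointData", pd)
    lines += data_block("CellData", cd)
    lines += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>", ""]
    Path(path).write_text("\n".join(lines))


def read_vtu(path) -> tuple[LabeledMesh, dict, dict]:
    """Read an ASCII .vtu written by :func:`write_vtu`.

    Returns ``(mesh, point_data, cell_data)`` with the tissue/fiber arrays
    consumed into the mesh and any additional arrays in the dicts.
    """
    root = ET.parse(str(path)).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK unstructured grid file")

    def parse(elem: ET.Element) -> np.ndarray:
        vals = np.array((elem.text or "").split(), dtype=np.float64)
        ncomp = int(elem.get("NumberOfComponents", "1"))
        if elem.get("type", "").startswith(("Int", "UInt")):
            vals = vals.astype(np.int64)
        return vals.reshape(-1, ncomp) if ncomp > 1 else vals

    nodes = parse(piece.find("./Points/DataArray"))
    arrays = {d.get("Name"): d for d in piece.findall("./Cells/DataArray")}
    types = parse(arrays["types"])
    if not np.all(types == _VTK_TET):
        raise ValueError(f"{path}: only tetrahedral cells are supported")
    elements = parse(arrays["connectivity"]).reshape(-1, 4)

    point_data, cell_data = {}, {}
    for section, store in (("PointData", point_data), ("CellData", cell_data)):
        sec = piece.find(section)
        if sec is not None:
            for d in sec.findall("DataArray"):
                store[d.get("Name")] = parse(d)

    tissue = cell_data.pop("tissue_class", np.zeros(elements.shape[0], dtype=np.int64))
    fiber = cell_data.pop("fiber", np.tile([1.0, 0.0, 0.0], (elements.shape[0], 1)))
    mesh = LabeledMesh(
        nodes=nodes,
        elements=elements,
        tissue_class=tissue,
        fiber=fiber,
        resolution_tag=Path(path).stem,
    )
    return mesh, point_data, cell_data
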