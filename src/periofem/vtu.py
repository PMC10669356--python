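"""Minimal ascii VTU (VTK XML unstructured grid) writer/reader.

Supports linear and quadratic tetrahedra with point and cell data, which
is all the package exports; readable by ParaView/VTK and by
:func:`read_vtu` for round-tripping.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

__all__ = ["write_vtu", "read_vtu"]

_CELL_TYPES = {4: 10, 10: 24}  # VTK_TETRA, VTK_QUADRATIC_TETRA


def _fmt(arr: np.ndarray) -> str:
    flat = np.asarray(arr).ravel()
    if flat.dtype.kind in "iu":
        return " ".join(str(int(v)) for v in flat)
    return " ".join(f"{v:.17g}" for v in flat)


def write_vtu(path, nodes: np.ndarray, elems: np.ndarray,
              point_data: dict | None = None,
              cell_data: dict | None = None) -> Path:
    """Write an ascii .vtu file; returns the path."""
    path = Path(path)
    n, m = len(nodes), len(elems)
    k = elems.shape[1]
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        '<UnstructuredGrid>',
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        '<Points>',
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(np.asarray(nodes, dtype=float)),
        '</DataArray>', '</Points>', '<Cells>',
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt(np.asarray(elems, dtype=np.int64)),
        '</DataArray>',
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt(np.arange(1, m + 1, dtype=np.int64) * k),
        '</DataArray>',
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _fmt(np.full(m, _CELL_TYPES[k], dtype=np.uint8)),
        '</DataArray>', '</Cells>',
    ]

    def data_block(tag, data):
        lines.append(f'<{tag}>')
        for name, arr in (data or {}).items():
            arr = np.asarray(arr)
            comps = 1 if arr.ndim == 1 else arr.shape[1]
            dtype = "Int64" if arr.dtype.kind in "iu" else "Float64"
            lines.append(
                f'<DataArray type="{dtype}" Name="{name}" '
                f'NumberOfComponents="{comps}" format="ascii">')
            lines.append(_fmt(arr))
            lines.append('</DataArray>')
        lines.append(f'</{tag}>')

    data_block("PointData", point_data)
    data_block("CellData", cell_data)
    lines += ['</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    path.write_text("\n".join(lines))
    return path


def read_vtu(path):
    """Read an ascii .vtu written by :func:`write_vtu`.

    Returns (nodes, elems, point_data, cell_data).
    """
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")

    def parse(elem, dtype=float):
        return np.fromstring(elem.text.strip().replace("\n", " "),
                             sep=" ", dtype=dtype)

    pts = parse(piece.find("Points/DataArray")).reshape(-1, 3)
    arrays = {d.get("Name"): d for d in piece.findall("Cells/DataArray")}
    conn = parse(arrays["connectivity"], dtype=float).astype(np.int64)
    offsets = parse(arrays["offsets"], dtype=float).astype(np.int64)
    k = offsets[0]
    elems = conn.reshape(-1, k)

    def read_data(tag):
        out = {}
        block = piece.find(tag)
        if block is None:
            return out
        for d in block.findall("DataArray"):
            arr = parse(d)
            comps = int(d.get("NumberOfComponents", "1"))
            if comps > 1:
                arr = arr.reshape(-1, comps)
            if d.get("type") == "Int64":
                arr = arr.astype(np.int64)
            out[d.get("Name")] = arr
        return out

    return pts, elems, read_data("PointData"), read_data("CellData")
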