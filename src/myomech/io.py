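"""Output writers: CSV time series, VTU field snapshots, fiber polylines.

VTU files are plain-XML (ascii) unstructured grids; elements are exported
through their 8 corner nodes (linear hexahedra) with per-element mean
fields as cell data, which standard mesh tooling reads directly.  A
minimal reader is provided for round-trip checks.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

__all__ = ["write_timeseries", "write_fields", "read_vtu_points",
           "write_fiber_vtk", "TIMESERIES_COLUMNS"]

TIMESERIES_COLUMNS = (
    "time_ms", "nominal_stress_kPa", "active_stress_kPa", "length_cm",
    "mean_Vm_mV", "mean_A2norm", "mean_gamma",
)


def write_timeseries(result, path) -> Path:
    """Write the per-CMM-step scalar trace as CSV (12 significant digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = result.table()
    lines = [",".join(TIMESERIES_COLUMNS)]
    n = len(cols["time_ms"])
    for i in range(n):
        lines.append(",".join(f"{cols[c][i]:.12g}"
                              for c in TIMESERIES_COLUMNS))
    path.write_text("\n".join(lines) + "\n")
    return path


# VTK linear hexahedron corner ordering from our lexicographic Q2 locals
_HEX_CORNERS = (0, 2, 8, 6, 18, 20, 26, 24)


def write_fields(mesh, u_field, path, *, p_field=None, point_data=None,
                 cell_data=None) -> Path:
    """Write deformed mesh + fields as an ascii VTU file.

    ``point_data``/``cell_data`` are name -> array mappings (per geometry
    node / per element).  Displacement is always included as point data.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    x = mesh.X + u_field
    npts = x.shape[0]
    ne = mesh.n_elements
    conn = mesh.conn[:, _HEX_CORNERS]
    pdata = {"displacement": u_field}
    if point_data:
        pdata.update(point_data)
    cdata = dict(cell_data or {})

    def arr(a, fmt="%.12g"):
        return " ".join(fmt % v for v in np.asarray(a).ravel())

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             "<UnstructuredGrid>",
             f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ne}">',
             "<Points>",
             '<DataArray type="Float64" NumberOfComponents="3" '
             'format="ascii">', arr(x), "</DataArray>", "</Points>",
             "<Cells>",
             '<DataArray type="Int64" Name="connectivity" format="ascii">',
             arr(conn, "%d"), "</DataArray>",
             '<DataArray type="Int64" Name="offsets" format="ascii">',
             arr(8 * (np.arange(ne) + 1), "%d"), "</DataArray>",
             '<DataArray type="UInt8" Name="types" format="ascii">',
             arr(np.full(ne, 12), "%d"), "</DataArray>", "</Cells>",
             "<PointData>"]
    for name, data in pdata.items():
        data = np.asarray(data, dtype=float)
        nc = 1 if data.ndim == 1 else data.shape[1]
        parts += [f'<DataArray type="Float64" Name="{name}" '
                  f'NumberOfComponents="{nc}" format="ascii">',
                  arr(data), "</DataArray>"]
    parts.append("</PointData>")
    parts.append("<CellData>")
    for name, data in cdata.items():
        parts += [f'<DataArray type="Float64" Name="{name}" '
                  'NumberOfComponents="1" format="ascii">',
                  arr(data), "</DataArray>"]
    parts += ["</CellData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(parts) + "\n")
    return path


def read_vtu_points(path) -> np.ndarray:
    """Read back the points block of a VTU file written by write_fields."""
    root = ET.parse(path).getroot()
    pts = root.find(".//Points/DataArray")
    vals = np.array(pts.text.split(), dtype=float)
    return vals.reshape(-1, 3)


def write_fiber_vtk(fibers, path) -> Path:
    """Export fiber node chains as a legacy-VTK polyline file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pts = np.concatenate([f.positions for f in fibers])
    lines = ["# vtk DataFile Version 3.0", "fibers", "ASCII",
             "DATASET POLYDATA", f"POINTS {pts.shape[0]} double"]
    lines += [" ".join(f"{v:.12g}" for v in p) for p in pts]
    total = sum(f.n_nodes + 1 for f in fibers)
    lines.append(f"LINES {len(fibers)} {total}")
    off = 0
    for f in fibers:
        lines.append(" ".join(
            [str(f.n_nodes)] + [str(off + i) for i in range(f.n_nodes)]))
        off += f.n_nodes
    path.write_text("\n".join(lines) + "\n")
    return path
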