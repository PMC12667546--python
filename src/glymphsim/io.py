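"""Export helpers: VTU (VTK unstructured-grid XML, ASCII) and CSV tables.

The VTU writer emits hexahedral cells for the structured grid with arbitrary
cell- and point-data arrays.  Coordinates are written in SI metres (the
package-internal unit is µm); velocities are exported in µm/s and pressures in
Pa for parity with the usual visualisation conventions.
"""
from __future__ import annotations

import os

import numpy as np

from .grid import UM, StructuredGrid


def _fmt(arr, per_line=6):
    flat = np.asarray(arr).ravel()
    return "\n".join(
        " ".join(f"{v:.9g}" for v in flat[i:i + per_line])
        for i in range(0, len(flat), per_line))


def write_vtu(path: str, grid: StructuredGrid, cell_data: dict | None = None,
              point_data: dict | None = None) -> None:
    """Write the grid as hexahedral VTU with the given data arrays.

    Cell data arrays must have shape ``grid.shape`` (or ``(*shape, 3)`` for
    vectors); point data shape ``(nx+1, ny+1, nz+1)`` likewise.
    """
    nx, ny, nz = grid.shape
    X, Y, Z = np.meshgrid(grid.x * UM, grid.y * UM, grid.z * UM, indexing="ij")
    npts = X.size
    ncells = nx * ny * nz

    def pid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    conn = np.stack([pid(I, J, K), pid(I + 1, J, K), pid(I + 1, J + 1, K),
                     pid(I, J + 1, K), pid(I, J, K + 1), pid(I + 1, J, K + 1),
                     pid(I + 1, J + 1, K + 1), pid(I, J + 1, K + 1)],
                    axis=-1).reshape(-1, 8)

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             '<UnstructuredGrid>',
             f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncells}">',
             '<Points>',
             '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
             _fmt(np.stack([X, Y, Z], axis=-1)),
             '</DataArray>', '</Points>', '<Cells>',
             '<DataArray type="Int64" Name="connectivity" format="ascii">',
             _fmt(conn, 8),
             '</DataArray>',
             '<DataArray type="Int64" Name="offsets" format="ascii">',
             _fmt(8 * np.arange(1, ncells + 1), 12),
             '</DataArray>',
             '<DataArray type="UInt8" Name="types" format="ascii">',
             _fmt(np.full(ncells, 12), 24),
             '</DataArray>', '</Cells>']

    def data_section(tag, data):
        out = [f'<{tag}>']
        for name, arr in (data or {}).items():
            arr = np.asarray(arr)
            ncomp = 1
            if arr.ndim == 4:
                ncomp = arr.shape[-1]
            out.append(f'<DataArray type="Float64" Name="{name}" '
                       f'NumberOfComponents="{ncomp}" format="ascii">')
            out.append(_fmt(arr.astype(float)))
            out.append('</DataArray>')
        out.append(f'</{tag}>')
        return out

    parts += data_section("CellData", cell_data)
    parts += data_section("PointData", point_data)
    parts += ['</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def export_mesh(mesh, path: str) -> None:
    """Mesh with region labels, exposure flags and fluid volume fractions."""
    write_vtu(path, mesh.grid, cell_data={
        "region": mesh.label.astype(float),
        "fus_exposed": mesh.exposed.astype(float),
        "fluid_fraction": mesh.vol_frac,
    })


def export_flow(mesh, flow, path: str) -> None:
    """Velocity (µm/s) and pressure (Pa) fields."""
    write_vtu(path, mesh.grid, cell_data={
        "velocity_um_s": flow.cell_velocity() / UM,
        "pressure_pa": flow.pressure,
        "region": mesh.label.astype(float),
    })


def export_concentration(mesh, c, path: str, name: str = "concentration") -> None:
    write_vtu(path, mesh.grid, cell_data={name: c})


def export_series_csv(series, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    series.to_dataframe().to_csv(path, index=False)
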