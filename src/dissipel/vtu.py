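"""Minimal ASCII XML VTU reader/writer for unstructured snapshot series.

Only what the pipeline needs: Float64 point coordinates, tetra/hex
connectivity, and named point-data arrays (3-component velocity, scalar
pressure, optional scalars such as ``DF``).  Files are plain-text
``format="ascii"`` DataArrays, round-tripping coordinates and fields to
better than 1e-9 relative.  Coordinates of meshes exported in millimetres
are rescaled on read via ``length_scale`` (e.g. 1e-3).
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FieldSeries, FieldSnapshot, ValidationError, VolumeMesh

__all__ = ["write_snapshot", "read_snapshot", "read_mesh", "write_series", "read_series"]

_VTK_CODES = {"tetra": 10, "hexahedron": 12}
_KIND_FROM_CODE = {v: k for k, v in _VTK_CODES.items()}


def _fmt(arr: np.ndarray) -> str:
    return "\n".join(" ".join(f"{v:.17g}" for v in row) for row in np.atleast_2d(arr))


def _data_array(name: str, arr: np.ndarray, dtype: str = "Float64") -> ET.Element:
    arr = np.atleast_2d(arr)
    el = ET.Element("DataArray", type=dtype, Name=name, format="ascii")
    if arr.shape[1] > 1 or name in ("velocity", "Points"):
        el.set("NumberOfComponents", str(arr.shape[1]))
    el.text = "\n" + _fmt(arr) + "\n"
    return el


def write_snapshot(
    path,
    snapshot: FieldSnapshot,
    velocity_name: str = "velocity",
    pressure_name: str = "pressure",
    extra_point_data: dict | None = None,
) -> None:
    mesh = snapshot.mesh
    conn, offsets, types = [], [], []
    off = 0
    for kind, cells in mesh.cells:
        conn.append(cells.ravel())
        off_block = off + np.arange(1, len(cells) + 1) * cells.shape[1]
        offsets.append(off_block)
        off = off_block[-1] if len(cells) else off
        types.append(np.full(len(cells), _VTK_CODES[kind]))
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(mesh.n_nodes), NumberOfCells=str(mesh.n_cells))
    pts_el = ET.SubElement(piece, "Points")
    pts_el.append(_data_array("Points", mesh.points))
    cells_el = ET.SubElement(piece, "Cells")
    cells_el.append(_data_array("connectivity", np.concatenate(conn)[:, None], "Int64"))
    cells_el.append(_data_array("offsets", np.concatenate(offsets)[:, None], "Int64"))
    cells_el.append(_data_array("types", np.concatenate(types)[:, None], "UInt8"))
    pd_el = ET.SubElement(piece, "PointData")
    pd_el.append(_data_array(velocity_name, snapshot.velocity))
    pd_el.append(_data_array(pressure_name, snapshot.pressure[:, None]))
    for name, arr in (extra_point_data or {}).items():
        pd_el.append(_data_array(name, np.asarray(arr)[:, None] if np.asarray(arr).ndim == 1 else arr))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _parse_array(el: ET.Element) -> np.ndarray:
    vals = np.array(el.text.split(), dtype=float)
    ncomp = int(el.get("NumberOfComponents", "1"))
    return vals.reshape(-1, ncomp) if ncomp > 1 else vals


def _read_piece(path) -> tuple[VolumeMesh, dict]:
    root = ET.parse(path).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValidationError(f"{path}: not a VTU UnstructuredGrid file")
    pts = _parse_array(piece.find("./Points/DataArray"))
    cells_el = {el.get("Name"): el for el in piece.findall("./Cells/DataArray")}
    conn = _parse_array(cells_el["connectivity"]).astype(np.intp).ravel()
    offsets = _parse_array(cells_el["offsets"]).astype(np.intp).ravel()
    types = _parse_array(cells_el["types"]).astype(int).ravel()
    blocks: list[tuple[str, list]] = []
    start = 0
    for off, code in zip(offsets, types):
        kind = _KIND_FROM_CODE.get(code)
        if kind is None:
            raise ValidationError(f"{path}: unsupported VTK cell type {code} "
                                  "(only tetra=10 and hexahedron=12; pre-split prisms)")
        cell = conn[start:off]
        if blocks and blocks[-1][0] == kind:
            blocks[-1][1].append(cell)
        else:
            blocks.append((kind, [cell]))
        start = off
    mesh_cells = [(k, np.array(c, dtype=np.intp)) for k, c in blocks]
    arrays = {el.get("Name"): _parse_array(el) for el in piece.findall("./PointData/DataArray")}
    return VolumeMesh(pts, mesh_cells), arrays


def read_mesh(path, length_scale: float = 1.0) -> VolumeMesh:
    mesh, _ = _read_piece(path)
    if length_scale != 1.0:
        mesh.points = mesh.points * length_scale
    return mesh


def read_snapshot(
    path,
    velocity_name: str = "velocity",
    pressure_name: str = "pressure",
    length_scale: float = 1.0,
    time: float = 0.0,
    mesh: VolumeMesh | None = None,
) -> FieldSnapshot:
    """Read one VTU snapshot; pass ``mesh`` to reuse a shared mesh object."""
    own_mesh, arrays = _read_piece(path)
    for name in (velocity_name, pressure_name):
        if name not in arrays:
            raise ValidationError(
                f"{path}: missing point-data array {name!r}; present: {sorted(arrays)}"
            )
    if mesh is None:
        mesh = own_mesh
        if length_scale != 1.0:
            mesh.points = mesh.points * length_scale
    else:
        if own_mesh.n_nodes != mesh.n_nodes or not np.allclose(
            own_mesh.points * length_scale, mesh.points, rtol=1e-9, atol=0
        ):
            raise ValidationError(f"{path}: mesh differs from the series mesh")
    vel = np.atleast_2d(arrays[velocity_name])
    if vel.shape != (mesh.n_nodes, 3):
        raise ValidationError(f"{path}: {velocity_name!r} is not a 3-component nodal array")
    return FieldSnapshot(mesh, time, vel, np.ravel(arrays[pressure_name]))


def write_series(directory, series: FieldSeries, basename: str = "snap",
                 manifest_name: str = "times.csv") -> Path:
    """Write one VTU per snapshot plus a (filename, time) CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, snap in enumerate(series.snapshots):
        fname = f"{basename}_{i:04d}.vtu"
        write_snapshot(directory / fname, snap)
        rows.append((fname, snap.time))
    manifest = directory / manifest_name
    pd.DataFrame(rows, columns=["filename", "time"]).to_csv(manifest, index=False)
    return manifest


def read_series(
    manifest_path,
    period: float,
    n_cycles: int = 1,
    velocity_name: str = "velocity",
    pressure_name: str = "pressure",
    length_scale: float = 1.0,
) -> FieldSeries:
    """Read a snapshot series from a CSV manifest of (filename, time).

    Rows are sorted by time (with a warning if the manifest was unordered);
    all files must share one mesh.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    if not {"filename", "time"} <= set(table.columns):
        raise ValidationError("manifest must have 'filename' and 'time' columns")
    if not table["time"].is_monotonic_increasing:
        warnings.warn("manifest times unordered; sorting by time", stacklevel=2)
        table = table.sort_values("time", kind="stable")
    snaps: list[FieldSnapshot] = []
    mesh: VolumeMesh | None = None
    for fname, t in zip(table["filename"], table["time"]):
        snap = read_snapshot(
            manifest_path.parent / fname, velocity_name, pressure_name,
            length_scale=length_scale, time=float(t), mesh=mesh,
        )
        mesh = snap.mesh
        snaps.append(snap)
    return FieldSeries(snaps, period=period, n_cycles=n_cycles)
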