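"""Core domain types: meshes, field snapshots, time series, fluid properties.

All quantities are strictly SI (m, s, kg, Pa, W).  Meshes exported in mm must
be converted on read via the ``length_scale`` option of the I/O layer; nothing
in this module rescales coordinates silently.

Two cell kinds are supported: linear tetrahedra and linear hexahedra (VTK node
ordering).  Hexahedra are decomposed into six tetrahedra around the 0-6
diagonal for volume computation and quadrature; the decomposition conserves
volume exactly for planar-faced cells.  Prism/wedge boundary-layer cells must
be pre-split to tetrahedra by the exporter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "VolumeMesh",
    "FieldSnapshot",
    "FieldSeries",
    "FluidProperties",
    "BLOOD",
    "compute_cell_volumes",
    "validate_series",
]


class ValidationError(ValueError):
    """Raised when a mesh, field or configuration violates its contract."""


#: VTK hexahedron (nodes 0-3 bottom quad, 4-7 top quad) split into six
#: positively oriented tetrahedra sharing the 0-6 diagonal.
HEX_TO_TETS = np.array(
    [
        [0, 1, 2, 6],
        [0, 2, 3, 6],
        [0, 3, 7, 6],
        [0, 7, 4, 6],
        [0, 4, 5, 6],
        [0, 5, 1, 6],
    ],
    dtype=np.intp,
)

_CELL_SIZES = {"tetra": 4, "hexahedron": 8}


def _tet_signed_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = points[tets[:, 0]]
    d1 = points[tets[:, 1]] - a
    d2 = points[tets[:, 2]] - a
    d3 = points[tets[:, 3]] - a
    return np.einsum("ij,ij->i", d1, np.cross(d2, d3)) / 6.0


@dataclass
class VolumeMesh:
    """Unstructured volume mesh: node coordinates plus cell blocks.

    Parameters
    ----------
    points
        ``(n_nodes, 3)`` node coordinates in metres.
    cells
        List of ``(kind, connectivity)`` blocks, ``kind`` in
        ``{"tetra", "hexahedron"}`` and connectivity of shape
        ``(n_cells_block, 4 or 8)``.
    grid_shape
        Optional ``(nx, ny, nz)`` for meshes whose nodes form a rectilinear
        grid in C order (x slowest); required by the structured gradient
        scheme.
    meta
        Free-form geometry metadata (e.g. pipe radius/length for analytic
        fixtures).
    """

    points: np.ndarray
    cells: list[tuple[str, np.ndarray]]
    grid_shape: tuple[int, int, int] | None = None
    meta: dict = field(default_factory=dict)
    _cell_volumes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("points must have shape (n_nodes, 3)")
        norm = []
        for kind, conn in self.cells:
            if kind not in _CELL_SIZES:
                raise ValidationError(f"unsupported cell kind {kind!r}")
            conn = np.ascontiguousarray(conn, dtype=np.intp)
            if conn.ndim != 2 or conn.shape[1] != _CELL_SIZES[kind]:
                raise ValidationError(f"{kind} connectivity must be (n, {_CELL_SIZES[kind]})")
            if conn.size and (conn.min() < 0 or conn.max() >= len(self.points)):
                raise ValidationError("cell connectivity references a node out of range")
            norm.append((kind, conn))
        self.cells = norm

    # -- basic queries -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return sum(len(conn) for _, conn in self.cells)

    def tetrahedralized(self) -> tuple[np.ndarray, np.ndarray]:
        """All cells as tetrahedra.

        Returns ``(tets, parent)`` where ``tets`` is ``(n_tets, 4)`` and
        ``parent[i]`` is the global index of the cell each tet came from.
        """
        blocks, parents = [], []
        offset = 0
        for kind, conn in self.cells:
            n = len(conn)
            if kind == "tetra":
                blocks.append(conn)
                parents.append(np.arange(offset, offset + n))
            else:  # hexahedron
                tets = conn[:, HEX_TO_TETS]  # (n, 6, 4)
                blocks.append(tets.reshape(-1, 4))
                parents.append(np.repeat(np.arange(offset, offset + n), 6))
            offset += n
        if not blocks:
            return np.empty((0, 4), dtype=np.intp), np.empty(0, dtype=np.intp)
        return np.vstack(blocks), np.concatenate(parents)

    def cell_centroids(self) -> np.ndarray:
        out = []
        for _, conn in self.cells:
            out.append(self.points[conn].mean(axis=1))
        return np.vstack(out) if out else np.empty((0, 3))

    @property
    def cell_volumes(self) -> np.ndarray:
        if self._cell_volumes is None:
            self._cell_volumes = compute_cell_volumes(self)
        return self._cell_volumes

    @property
    def total_volume(self) -> float:
        return float(self.cell_volumes.sum())


def compute_cell_volumes(mesh: VolumeMesh, degenerate_rtol: float = 1e-12) -> np.ndarray:
    """Per-cell volumes in m^3.

    Hexahedra are split into six tetrahedra (``HEX_TO_TETS``) and the signed
    sub-volumes summed, which is exact for planar faces and robust for mildly
    warped ones.  A cell whose volume is non-positive (or vanishes relative to
    the domain scale) is reported as degenerate by its global index.
    """
    tets, parent = mesh.tetrahedralized()
    if len(tets) == 0:
        raise ValidationError("mesh has no cells")
    sub = _tet_signed_volumes(mesh.points, tets)
    vols = np.bincount(parent, weights=sub, minlength=mesh.n_cells)
    scale = max(vols.max(initial=0.0), abs(vols).max())
    bad = np.nonzero(vols <= degenerate_rtol * scale)[0]
    if bad.size:
        raise ValidationError(f"degenerate cell (zero or negative volume): index {int(bad[0])}")
    return vols


@dataclass
class FieldSnapshot:
    """Velocity + pressure on a mesh at one time instant."""

    mesh: VolumeMesh
    time: float
    velocity: np.ndarray  # (n_nodes, 3) m/s
    pressure: np.ndarray  # (n_nodes,) Pa

    def __post_init__(self) -> None:
        self.velocity = np.ascontiguousarray(self.velocity, dtype=float)
        self.pressure = np.ascontiguousarray(self.pressure, dtype=float)
        n = self.mesh.n_nodes
        if self.velocity.shape != (n, 3):
            raise ValidationError(f"velocity must have shape ({n}, 3)")
        if self.pressure.shape != (n,):
            raise ValidationError(f"pressure must have shape ({n},)")
        if not np.isfinite(self.time):
            raise ValidationError("snapshot time must be finite")


@dataclass
class FieldSeries:
    """Time-ordered snapshots spanning ``n_cycles`` cardiac cycles."""

    snapshots: list[FieldSnapshot]
    period: float
    n_cycles: int = 1
    t0: float | None = None

    def __post_init__(self) -> None:
        if self.t0 is None and self.snapshots:
            self.t0 = self.snapshots[0].time

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    @property
    def mesh(self) -> VolumeMesh:
        return self.snapshots[0].mesh


def validate_series(series: FieldSeries) -> list[str]:
    """Check a series; returns a list of human-readable issues (empty = valid).

    An empty series is a hard error; everything else is reported so a caller
    can decide whether to proceed.
    """
    if not series.snapshots:
        raise ValidationError("empty series")
    issues: list[str] = []
    times = series.times
    if np.any(np.diff(times) <= 0):
        issues.append("non-monotone time: snapshot times must be strictly increasing")
    mesh = series.snapshots[0].mesh
    for i, snap in enumerate(series.snapshots):
        if snap.mesh is not mesh and not (
            snap.mesh.n_nodes == mesh.n_nodes and np.allclose(snap.mesh.points, mesh.points)
        ):
            issues.append(f"mesh mismatch at snapshot {i}")
        if not (np.all(np.isfinite(snap.velocity)) and np.all(np.isfinite(snap.pressure))):
            issues.append(f"non-finite field at snapshot {i}")
    if series.period <= 0:
        issues.append("period must be positive")
    else:
        span = times[-1] - times[0]
        step = np.median(np.diff(times)) if len(times) > 1 else series.period
        if abs(span - series.n_cycles * series.period) > step * (1 + 1e-9):
            issues.append(
                f"series span {span:.6g}s does not cover n*period = "
                f"{series.n_cycles * series.period:.6g}s within one step"
            )
    return issues


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density (kg/m^3) and dynamic viscosity (Pa.s)."""

    density: float = 1060.0
    dynamic_viscosity: float = 0.004

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValidationError("density and dynamic viscosity must be positive")


#: Blood modelled as an incompressible Newtonian fluid under laminar flow.
BLOOD = FluidProperties(density=1060.0, dynamic_viscosity=0.004)
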