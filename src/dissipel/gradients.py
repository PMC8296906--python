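"""Velocity-gradient tensor evaluation on structured grids and unstructured meshes.

The gradient tensor is stored per node as ``G[i, j] = d(u_i)/d(x_j)`` in 1/s.
Three schemes are provided:

``structured``
    2nd-order central differences in the interior, 2nd-order one-sided at the
    boundary (``numpy.gradient`` with ``edge_order=2``); requires the mesh to
    carry a rectilinear ``grid_shape``.
``wlsq``
    Node-centred weighted least squares over the edge-connected 1-ring with
    inverse-distance weights.  Exact for globally linear fields; the default
    on unstructured meshes because the dissipation function is evaluated at
    the nodes where the fields live.
``green_gauss``
    Cell-based exact linear-shape-function gradient on tetrahedra (the
    Green–Gauss identity specialised to simplices), volume-averaged to nodes;
    retained as an independent cross-check of the wlsq scheme.

No-slip wall nodes need no ghost treatment: their 1-ring reaches interior
nodes, which yields the one-sided stencil implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FieldSnapshot, ValidationError, VolumeMesh

__all__ = [
    "GradientField",
    "gradient_structured",
    "gradient_unstructured",
    "gradient_green_gauss",
    "compute_gradients",
]


@dataclass
class GradientField:
    """Per-node 3x3 velocity-gradient tensors, units 1/s."""

    mesh: VolumeMesh
    tensors: np.ndarray  # (n_nodes, 3, 3)

    def __post_init__(self) -> None:
        self.tensors = np.ascontiguousarray(self.tensors, dtype=float)
        if self.tensors.shape != (self.mesh.n_nodes, 3, 3):
            raise ValidationError("tensors must have shape (n_nodes, 3, 3)")


def gradient_structured(snapshot: FieldSnapshot, spacing=None) -> GradientField:
    """Finite-difference gradients on a rectilinear grid.

    ``spacing`` may be a per-axis step or omitted to use the node coordinates
    directly (which also handles non-uniform rectilinear grids).
    """
    mesh = snapshot.mesh
    if mesh.grid_shape is None:
        raise ValidationError("mesh carries no grid_shape; use an unstructured scheme")
    nx, ny, nz = mesh.grid_shape
    if min(nx, ny, nz) < 3:
        raise ValidationError("structured gradients need >= 3 nodes per axis")
    if nx * ny * nz != mesh.n_nodes:
        raise ValidationError("grid_shape inconsistent with node count")
    if spacing is None:
        pts = mesh.points.reshape(nx, ny, nz, 3)
        axes = (pts[:, 0, 0, 0], pts[0, :, 0, 1], pts[0, 0, :, 2])
    else:
        axes = tuple(float(s) for s in np.broadcast_to(spacing, (3,)))
    tensors = np.empty((mesh.n_nodes, 3, 3))
    for i in range(3):
        comp = snapshot.velocity[:, i].reshape(nx, ny, nz)
        dx, dy, dz = np.gradient(comp, *axes, edge_order=2)
        tensors[:, i, 0] = dx.ravel()
        tensors[:, i, 1] = dy.ravel()
        tensors[:, i, 2] = dz.ravel()
    return GradientField(mesh, tensors)


def _edge_list(mesh: VolumeMesh) -> np.ndarray:
    """Unique undirected node-pair edges of all cells."""
    tet_edges = np.array([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
    hex_edges = np.array(
        [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4),
         (0, 4), (1, 5), (2, 6), (3, 7)]
    )
    pairs = []
    for kind, conn in mesh.cells:
        e = tet_edges if kind == "tetra" else hex_edges
        pairs.append(conn[:, e].reshape(-1, 2))
    edges = np.vstack(pairs)
    edges = np.sort(edges, axis=1)
    return np.unique(edges, axis=0)


def gradient_unstructured(
    mesh: VolumeMesh,
    snapshot: FieldSnapshot,
    weight_power: float = 1.0,
    rank_rtol: float = 1e-8,
) -> GradientField:
    """Node-centred weighted-least-squares gradient over the 1-ring.

    Solves, per node ``i``, ``min sum_j w_ij |G (x_j - x_i) - (u_j - u_i)|^2``
    over edge neighbours ``j`` with weights ``w_ij = |x_j - x_i|^-p``.
    Exact for globally linear fields.  Raises if some node's neighbourhood is
    rank deficient (fewer than 3 independent directions); the cell-based
    Green–Gauss scheme is the documented fallback for such meshes.
    """
    edges = _edge_list(mesh)
    # both directions
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    d = mesh.points[dst] - mesh.points[src]
    dist = np.linalg.norm(d, axis=1)
    if np.any(dist == 0):
        raise ValidationError("coincident nodes share an edge")
    w = dist ** (-weight_power)
    n = mesh.n_nodes
    # normal-equation blocks A = sum w d d^T (n,3,3), B[:, :, k] = sum w d du_k
    A = np.zeros((n, 3, 3))
    B = np.zeros((n, 3, 3))
    du = snapshot.velocity[dst] - snapshot.velocity[src]
    wd = w[:, None] * d
    for a in range(3):
        for b in range(a, 3):
            acc = np.bincount(src, weights=wd[:, a] * d[:, b], minlength=n)
            A[:, a, b] = acc
            A[:, b, a] = acc
        for k in range(3):
            B[:, a, k] = np.bincount(src, weights=wd[:, a] * du[:, k], minlength=n)
    eig = np.linalg.eigvalsh(A)
    bad = np.nonzero(eig[:, 0] <= rank_rtol * np.maximum(eig[:, -1], 0))[0]
    if bad.size:
        raise ValidationError(
            f"rank-deficient neighborhood (coplanar neighbors) at node {int(bad[0])}; "
            "consider the green_gauss scheme"
        )
    X = np.linalg.solve(A, B)  # X[:, :, k] = grad of component k
    return GradientField(mesh, X.transpose(0, 2, 1).copy())


def gradient_green_gauss(mesh: VolumeMesh, snapshot: FieldSnapshot) -> GradientField:
    """Cell-based gradients (exact on linear tet shape functions), averaged to nodes.

    Hexahedra are decomposed into tetrahedra first.  The node value is the
    volume-weighted mean of the gradients of all incident (sub-)cells.
    """
    tets, _ = mesh.tetrahedralized()
    p0 = mesh.points[tets[:, 0]]
    M = np.stack([mesh.points[tets[:, k]] - p0 for k in (1, 2, 3)], axis=1)  # (T,3,3)
    vol = np.abs(np.linalg.det(M)) / 6.0
    ok = vol > 0
    dU = np.stack([snapshot.velocity[tets[:, k]] - snapshot.velocity[tets[:, 0]] for k in (1, 2, 3)], axis=1)
    G_cell = np.zeros((len(tets), 3, 3))
    # u(x) = u0 + G (x - x0): rows of M map to rows of dU -> G = (M^-1)^T applied
    G_cell[ok] = np.linalg.solve(M[ok], dU[ok]).transpose(0, 2, 1)
    n = mesh.n_nodes
    tensors = np.zeros((n, 3, 3))
    wsum = np.zeros(n)
    for k in range(4):
        idx = tets[:, k]
        np.add.at(wsum, idx, vol)
        for a in range(3):
            for b in range(3):
                np.add.at(tensors[:, a, b], idx, vol * G_cell[:, a, b])
    if np.any(wsum == 0):
        raise ValidationError("isolated node with no incident cell")
    return GradientField(mesh, tensors / wsum[:, None, None])


def compute_gradients(
    snapshot: FieldSnapshot,
    scheme: str = "wlsq",
    spacing=None,
) -> GradientField:
    """Dispatch on ``gradient.scheme`` config values {wlsq, green_gauss, structured}."""
    if scheme == "wlsq":
        return gradient_unstructured(snapshot.mesh, snapshot)
    if scheme == "green_gauss":
        return gradient_green_gauss(snapshot.mesh, snapshot)
    if scheme == "structured":
        return gradient_structured(snapshot, spacing=spacing)
    raise ValidationError(f"unknown gradient scheme {scheme!r}")
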