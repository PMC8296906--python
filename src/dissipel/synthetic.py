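"""Analytic flow fixtures with closed-form dissipation oracles.

Everything the post-processing pipeline consumes can be generated here
without a CFD solver: pipe and box meshes, steady and quasi-steady pulsatile
Poiseuille fields, null fixtures (uniform flow, rigid rotation), planar
Couette shear, and an idealized sidewall-aneurysm fixture with a prescribed
sac vortex.  Each fixture comes with the analytic quantity the discrete
pipeline must converge to:

* steady Poiseuille pipe: DP = 8*pi*mu*Vbar^2*L, pressure drop 8*mu*L*Vbar/R^2;
* Couette gap h, wall speed U: DF = mu*(U/h)^2 everywhere;
* uniform flow / rigid rotation: DF = 0;
* sac vortex: DP by exact-geometry spherical quadrature of the analytic DF.

The pulsatile series is quasi-steady (a steady profile rescaled by the
waveform): deliberately no unsteady inertia, hence no phase lag between the
inlet waveform and DP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .core import BLOOD, FieldSeries, FieldSnapshot, FluidProperties, ValidationError, VolumeMesh
from .gradients import GradientField
from .segmentation import PlaneSpec

__all__ = [
    "WaveformSpec",
    "make_pipe_mesh",
    "make_box_mesh",
    "poiseuille_snapshot",
    "poiseuille_gradient",
    "analytic_poiseuille_dp",
    "pulsatile_series",
    "uniform_snapshot",
    "uniform_gradient",
    "rigid_rotation_snapshot",
    "rigid_rotation_gradient",
    "couette_snapshot",
    "couette_gradient",
    "AneurysmFixture",
    "idealized_aneurysm_fixture",
    "sac_dp_quadrature",
]


# ---------------------------------------------------------------------------
# waveform
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class WaveformSpec:
    """Inlet mean-velocity waveform V(t) for quasi-steady pulsatile series.

    Defaults follow a cardiac cycle of 0.8 s sampled at 0.01 s.  The default
    shape is a single-harmonic sinusoid ``V0*(1 + a*sin(2*pi*t/T))`` — a
    unimodal stand-in for a measured Doppler waveform (rise in systole, decay
    in diastole).  ``amplitude`` must stay below 1 so velocity stays positive.
    """

    base_velocity: float = 0.3
    shape: str = "sinusoid"  # constant | sinusoid | tabulated
    amplitude: float = 0.5
    period: float = 0.8
    step: float = 0.01
    seed: int = 0
    table: tuple | None = None  # (times, multipliers), one period

    def __post_init__(self) -> None:
        if self.period <= 0 or self.step <= 0:
            raise ValidationError("period and step must be positive")
        ratio = self.period / self.step
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ValidationError("step must divide period")
        if not (0 <= self.amplitude < 1):
            raise ValidationError("amplitude fraction must be in [0, 1)")
        if self.shape == "tabulated" and self.table is None:
            raise ValidationError("tabulated waveform needs a table")
        if self.shape not in ("constant", "sinusoid", "tabulated"):
            raise ValidationError(f"unknown waveform shape {self.shape!r}")

    def times(self, n_cycles: int = 1) -> np.ndarray:
        n = int(round(self.period / self.step)) * n_cycles
        return np.arange(n + 1) * self.step

    def mean_velocity(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.shape == "constant":
            return np.full_like(t, self.base_velocity)
        if self.shape == "sinusoid":
            return self.base_velocity * (1 + self.amplitude * np.sin(2 * np.pi * t / self.period))
        tt, mult = self.table
        return self.base_velocity * np.interp(np.mod(t, self.period), tt, mult, period=self.period)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------
def _disk_points(radius: float, m: int) -> np.ndarray:
    """Spiderweb point layout: ring k of m has 6k points at radius R*k/m."""
    pts = [(0.0, 0.0)]
    for k in range(1, m + 1):
        n = 6 * k
        phi = 2 * np.pi * (np.arange(n) + 0.5 * (k % 2)) / n
        r = radius * k / m
        pts.extend(zip(r * np.cos(phi), r * np.sin(phi)))
    return np.asarray(pts)


def _fix_orientation(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = points[tets[:, 0]]
    vol6 = np.einsum(
        "ij,ij->i",
        points[tets[:, 1]] - a,
        np.cross(points[tets[:, 2]] - a, points[tets[:, 3]] - a),
    )
    flip = vol6 < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return tets


def make_pipe_mesh(radius: float, length: float, resolution: int = 16) -> VolumeMesh:
    """Tetrahedral cylinder mesh along x, spanning ``[0, length]``.

    ``resolution`` is the approximate number of cells across the diameter
    (must be >= 8).  Built by Delaunay-triangulating a spiderweb disk and
    extruding the triangles into prisms, each split into three tetrahedra.
    The discrete cross-section is an inscribed polygon, so the volume is
    within ~0.5% of pi*R^2*L at resolution 16 and converges quadratically.
    """
    if radius <= 0 or length <= 0:
        raise ValidationError("radius and length must be positive")
    if resolution < 8:
        raise ValidationError("pipe resolution must be >= 8 cells across the diameter")
    m = resolution // 2
    disk = _disk_points(radius, m)
    tris = Delaunay(disk).simplices
    npd = len(disk)
    n_axial = max(2, int(round(length / (radius / m))))
    xs = np.linspace(0.0, length, n_axial + 1)
    pts = np.empty((len(xs) * npd, 3))
    for l, x in enumerate(xs):
        pts[l * npd : (l + 1) * npd, 0] = x
        pts[l * npd : (l + 1) * npd, 1] = disk[:, 0]
        pts[l * npd : (l + 1) * npd, 2] = disk[:, 1]
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    tet_blocks = []
    for l in range(n_axial):
        lo, hi = l * npd, (l + 1) * npd
        a0, b0, c0 = a + lo, b + lo, c + lo
        a1, b1, c1 = a + hi, b + hi, c + hi
        tet_blocks.append(np.stack([a0, b0, c0, a1], axis=1))
        tet_blocks.append(np.stack([b0, c0, a1, b1], axis=1))
        tet_blocks.append(np.stack([c0, a1, b1, c1], axis=1))
    tets = _fix_orientation(pts, np.vstack(tet_blocks))
    mesh = VolumeMesh(
        pts,
        [("tetra", tets)],
        meta={"kind": "pipe", "pipe_radius": radius, "pipe_length": length, "axis": "x"},
    )
    mesh.cell_volumes  # validate now: fails fast on a degenerate extrusion
    return mesh


def make_box_mesh(lengths, shape) -> VolumeMesh:
    """Structured hexahedral box mesh on ``[0, Lx] x [0, Ly] x [0, Lz]``.

    Node ordering is C order with x slowest, matching ``grid_shape`` used by
    the structured gradient scheme.
    """
    nx, ny, nz = (int(s) for s in shape)
    if min(nx, ny, nz) < 2:
        raise ValidationError("box mesh needs >= 2 nodes per axis")
    lx, ly, lz = (float(v) for v in lengths)
    x, y, z = (np.linspace(0, L, n) for L, n in ((lx, nx), (ly, ny), (lz, nz)))
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    hexes = np.stack(
        [
            nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
            nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
        ],
        axis=1,
    )
    return VolumeMesh(pts, [("hexahedron", hexes)], grid_shape=(nx, ny, nz),
                      meta={"kind": "box", "lengths": (lx, ly, lz)})


# ---------------------------------------------------------------------------
# analytic snapshots
# ---------------------------------------------------------------------------
def _require_pipe(mesh: VolumeMesh) -> tuple[float, float]:
    if mesh.meta.get("kind") != "pipe":
        raise ValidationError("snapshot requires a pipe mesh from make_pipe_mesh")
    return mesh.meta["pipe_radius"], mesh.meta["pipe_length"]


def poiseuille_snapshot(
    mesh: VolumeMesh,
    mean_velocity: float,
    props: FluidProperties = BLOOD,
    p0: float = 0.0,
    time: float = 0.0,
) -> FieldSnapshot:
    """Steady fully developed laminar pipe flow.

    ``u_x(r) = 2*Vbar*(1 - r^2/R^2)``, transverse components zero, pressure
    ``p(x) = p0 - (8*mu*Vbar/R^2)*x`` (Hagen–Poiseuille).  Divergence-free and
    no-slip at the wall.
    """
    R, _ = _require_pipe(mesh)
    r2 = mesh.points[:, 1] ** 2 + mesh.points[:, 2] ** 2
    vel = np.zeros((mesh.n_nodes, 3))
    vel[:, 0] = 2 * mean_velocity * np.clip(1 - r2 / R**2, 0.0, None)
    dpdx = 8 * props.dynamic_viscosity * mean_velocity / R**2
    pressure = p0 - dpdx * mesh.points[:, 0]
    return FieldSnapshot(mesh, time, vel, pressure)


def poiseuille_gradient(mesh: VolumeMesh, mean_velocity: float) -> GradientField:
    """Exact velocity-gradient field of the Poiseuille profile (du/dr = -4*Vbar*r/R^2)."""
    R, _ = _require_pipe(mesh)
    G = np.zeros((mesh.n_nodes, 3, 3))
    # tolerance keeps wall nodes (r = R to roundoff) on the inside branch
    inside = mesh.points[:, 1] ** 2 + mesh.points[:, 2] ** 2 <= R**2 * (1 + 1e-9)
    G[inside, 0, 1] = -4 * mean_velocity * mesh.points[inside, 1] / R**2
    G[inside, 0, 2] = -4 * mean_velocity * mesh.points[inside, 2] / R**2
    return GradientField(mesh, G)


def analytic_poiseuille_dp(props: FluidProperties, mean_velocity: float, length: float) -> float:
    """Closed-form dissipation power of steady Poiseuille flow: 8*pi*mu*Vbar^2*L.

    Follows from DF(r) = 16*mu*Vbar^2*r^2/R^4 integrated over the cylinder,
    and equals the Bernoulli balance m_dot*dp/rho — the two methods agree
    exactly for this flow.
    """
    if props.dynamic_viscosity <= 0 or mean_velocity is None or length <= 0:
        raise ValidationError("inputs must be positive")
    return 8 * np.pi * props.dynamic_viscosity * mean_velocity**2 * length


def pulsatile_series(
    mesh: VolumeMesh,
    waveform: WaveformSpec,
    props: FluidProperties = BLOOD,
    n_cycles: int = 1,
) -> FieldSeries:
    """Quasi-steady pulsatile Poiseuille series: one snapshot per waveform step."""
    times = waveform.times(n_cycles)
    vbars = waveform.mean_velocity(times)
    snaps = [
        poiseuille_snapshot(mesh, float(v), props, time=float(t))
        for t, v in zip(times, vbars)
    ]
    return FieldSeries(snaps, period=waveform.period, n_cycles=n_cycles)


def uniform_snapshot(mesh: VolumeMesh, velocity=(0.3, 0.0, 0.0), time: float = 0.0) -> FieldSnapshot:
    """Uniform translation — zero gradients, DF identically zero."""
    vel = np.broadcast_to(np.asarray(velocity, float), (mesh.n_nodes, 3)).copy()
    return FieldSnapshot(mesh, time, vel, np.zeros(mesh.n_nodes))


def uniform_gradient(mesh: VolumeMesh) -> GradientField:
    return GradientField(mesh, np.zeros((mesh.n_nodes, 3, 3)))


def rigid_rotation_snapshot(
    mesh: VolumeMesh, omega: float, center=None, time: float = 0.0
) -> FieldSnapshot:
    """Solid-body rotation about a z-axis through ``center``: u = omega x r.

    The gradient tensor is purely antisymmetric, so DF vanishes identically —
    rotation without deformation dissipates nothing.
    """
    c = np.zeros(3) if center is None else np.asarray(center, float)
    d = mesh.points - c
    vel = np.stack([-omega * d[:, 1], omega * d[:, 0], np.zeros(mesh.n_nodes)], axis=1)
    return FieldSnapshot(mesh, time, vel, np.zeros(mesh.n_nodes))


def rigid_rotation_gradient(mesh: VolumeMesh, omega: float) -> GradientField:
    G = np.zeros((mesh.n_nodes, 3, 3))
    G[:, 0, 1] = -omega
    G[:, 1, 0] = omega
    return GradientField(mesh, G)


def couette_snapshot(mesh: VolumeMesh, wall_speed: float, time: float = 0.0) -> FieldSnapshot:
    """Planar Couette flow across the mesh's y extent: u_x = U*(y-y0)/h.

    Constant shear rate U/h, so DF = mu*(U/h)^2 at every point.
    """
    y = mesh.points[:, 1]
    y0, y1 = float(y.min()), float(y.max())
    if y1 <= y0:
        raise ValidationError("mesh has zero extent in y")
    vel = np.zeros((mesh.n_nodes, 3))
    vel[:, 0] = wall_speed * (y - y0) / (y1 - y0)
    return FieldSnapshot(mesh, time, vel, np.zeros(mesh.n_nodes))


def couette_gradient(mesh: VolumeMesh, wall_speed: float) -> GradientField:
    y = mesh.points[:, 1]
    G = np.zeros((mesh.n_nodes, 3, 3))
    G[:, 0, 1] = wall_speed / (float(y.max()) - float(y.min()))
    return GradientField(mesh, G)


# ---------------------------------------------------------------------------
# idealized sidewall aneurysm
# ---------------------------------------------------------------------------
@dataclass
class AneurysmFixture:
    """Straight parent vessel with a spherical sidewall sac, plus its
    matched non-aneurysm counterpart.

    The sac domain is the convex region {|p - c| <= Rs, y >= Rp} — a sphere
    cut by the tangent plane of the pipe wall — whose centre sits at
    ``y = Rp + sqrt(Rs^2 - Rn^2)`` so the cut disk has exactly the neck
    radius Rn.  The prescribed blended field is continuous everywhere: the
    parent Poiseuille profile vanishes at r = Rp, and the sac vortex envelope
    vanishes both on the sphere surface and on the neck plane.  The vortex is
    prescribed, not a Navier–Stokes solution; its dissipation oracle is
    exact-geometry spherical quadrature (``sac_dp_quadrature``).
    """

    mesh: VolumeMesh
    non_aneurysm_mesh: VolumeMesh
    pipe_radius: float
    pipe_length: float
    sac_radius: float
    neck_radius: float
    sac_center: np.ndarray
    mean_velocity: float
    vortex_strength: float
    sac_cell_mask: np.ndarray = field(repr=False)
    segment_ids: np.ndarray = field(repr=False)  # ground truth, 0/1/2
    boundary_planes: tuple = ()
    planes: dict = field(default_factory=dict)

    # -- prescribed fields -------------------------------------------------
    def velocity(self, pts: np.ndarray, scale: float = 1.0) -> np.ndarray:
        pts = np.asarray(pts, float)
        Rp, Rs = self.pipe_radius, self.sac_radius
        r2 = pts[:, 1] ** 2 + pts[:, 2] ** 2
        vel = np.zeros_like(pts)
        vel[:, 0] = 2 * self.mean_velocity * np.clip(1 - r2 / Rp**2, 0.0, None)
        d = pts - self.sac_center
        e = np.clip(1 - np.einsum("ij,ij->i", d, d) / Rs**2, 0.0, None)
        g = np.clip((pts[:, 1] - Rp) / Rs, 0.0, None)
        f = self.vortex_strength * e * g
        vel[:, 1] -= f * d[:, 2]
        vel[:, 2] += f * d[:, 1]
        return scale * vel

    def pressure(self, pts: np.ndarray, props: FluidProperties = BLOOD, scale: float = 1.0,
                 p0: float = 0.0) -> np.ndarray:
        pts = np.asarray(pts, float)
        Rp = self.pipe_radius
        dpdx = 8 * props.dynamic_viscosity * self.mean_velocity * scale / Rp**2
        x = np.where(pts[:, 1] ** 2 + pts[:, 2] ** 2 <= Rp**2, pts[:, 0], self.sac_center[0])
        return p0 - dpdx * x

    def gradient(self, pts: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Exact (N, 3, 3) velocity-gradient tensors of the prescribed field."""
        pts = np.asarray(pts, float)
        Rp, Rs, A = self.pipe_radius, self.sac_radius, self.vortex_strength
        G = np.zeros((len(pts), 3, 3))
        inside = pts[:, 1] ** 2 + pts[:, 2] ** 2 <= Rp**2 * (1 + 1e-9)
        G[inside, 0, 1] = -4 * self.mean_velocity * pts[inside, 1] / Rp**2
        G[inside, 0, 2] = -4 * self.mean_velocity * pts[inside, 2] / Rp**2
        d = pts - self.sac_center
        e = 1 - np.einsum("ij,ij->i", d, d) / Rs**2
        g = (pts[:, 1] - Rp) / Rs
        # closed-domain interior limit: points exactly on the sphere surface
        # or neck plane get the one-sided gradient from inside the sac
        act = (e >= 0) & (g >= 0)
        if act.any():
            da, ea, ga = d[act], e[act], g[act]
            f = A * ea * ga
            grad_f = A * (ga[:, None] * (-2 * da / Rs**2))
            grad_f[:, 1] += A * ea / Rs
            # u_y = -f*dz, u_z = +f*dy
            Gy = -grad_f * da[:, 2:3]
            Gz = grad_f * da[:, 1:2]
            Gy[:, 2] -= f
            Gz[:, 1] += f
            G[act, 1, :] += Gy
            G[act, 2, :] += Gz
        return scale * G

    # -- snapshots / series ------------------------------------------------
    def snapshot(self, props: FluidProperties = BLOOD, scale: float = 1.0,
                 time: float = 0.0) -> FieldSnapshot:
        return FieldSnapshot(
            self.mesh, time, self.velocity(self.mesh.points, scale),
            self.pressure(self.mesh.points, props, scale),
        )

    def non_aneurysm_snapshot(self, props: FluidProperties = BLOOD, scale: float = 1.0,
                              time: float = 0.0) -> FieldSnapshot:
        m = self.non_aneurysm_mesh
        return poiseuille_snapshot(m, self.mean_velocity * scale, props, time=time)

    def series(self, waveform: WaveformSpec, props: FluidProperties = BLOOD,
               n_cycles: int = 1, aneurysm: bool = True) -> FieldSeries:
        times = waveform.times(n_cycles)
        scales = waveform.mean_velocity(times) / waveform.base_velocity
        make = self.snapshot if aneurysm else self.non_aneurysm_snapshot
        snaps = [make(props, float(s), float(t)) for t, s in zip(times, scales)]
        return FieldSeries(snaps, period=waveform.period, n_cycles=n_cycles)


def _cap_mesh(center: np.ndarray, Rs: float, Rp: float, Rn: float, h: float,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Tet-mesh the convex region {|p-c| <= Rs, y >= Rp} by point seeding + Delaunay."""
    cx, cy, cz = center
    # interior lattice with a small deterministic jitter (avoids cospherical
    # degeneracies of a perfectly regular lattice)
    ax = np.arange(-Rs, Rs + h / 2, h)
    X, Y, Z = np.meshgrid(cx + ax, cy + ax, cz + ax, indexing="ij")
    lat = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    lat = lat + rng.uniform(-0.05 * h, 0.05 * h, lat.shape)
    d = np.linalg.norm(lat - center, axis=1)
    lat = lat[(d <= Rs - 0.4 * h) & (lat[:, 1] >= Rp + 0.4 * h)]
    # sphere surface (Fibonacci), kept above the neck plane
    n_s = max(128, int(4 * np.pi * Rs**2 / h**2))
    i = np.arange(n_s)
    phi = np.pi * (3 - np.sqrt(5)) * i
    yy = 1 - 2 * (i + 0.5) / n_s
    rr = np.sqrt(np.clip(1 - yy**2, 0, None))
    sph = center + Rs * np.stack([rr * np.cos(phi), yy, rr * np.sin(phi)], axis=1)
    sph = sph[sph[:, 1] >= Rp + 0.2 * h]
    # neck rim circle and neck disk (spiderweb) in the plane y = Rp
    n_rim = max(16, int(2 * np.pi * Rn / h))
    ang = 2 * np.pi * np.arange(n_rim) / n_rim
    rim = np.stack([cx + Rn * np.cos(ang), np.full(n_rim, Rp), cz + Rn * np.sin(ang)], axis=1)
    m_n = max(2, int(round(Rn / h)))
    disk2 = _disk_points(Rn * (1 - 0.5 / m_n), m_n)  # strictly inside the rim
    disk = np.stack([cx + disk2[:, 0], np.full(len(disk2), Rp), cz + disk2[:, 1]], axis=1)
    pts = np.vstack([lat, sph, rim, disk])
    tets = Delaunay(pts).simplices
    tets = _fix_orientation(pts, tets)
    a = pts[tets[:, 0]]
    vol6 = np.einsum("ij,ij->i", pts[tets[:, 1]] - a,
                     np.cross(pts[tets[:, 2]] - a, pts[tets[:, 3]] - a))
    keep = vol6 > 1e-10 * h**3  # drop exactly degenerate hull slivers
    return pts, tets[keep]


def idealized_aneurysm_fixture(
    pipe_radius: float = 2e-3,
    sac_radius: float = 2e-3,
    neck_radius: float = 1e-3,
    resolution: int = 16,
    seed: int = 0,
    mean_velocity: float = 0.3,
    pipe_length: float | None = None,
    vortex_strength: float | None = None,
) -> AneurysmFixture:
    """Build the labeled sidewall-aneurysm fixture and its straight-pipe twin.

    ``resolution`` is cells across the parent-vessel diameter.  Cells carry
    ground-truth segment labels; the neck plane (C), a flow-normal plane (B)
    and a free orthogonal plane (A) are included, along with the two
    segment-boundary planes at ``x = cx -/+ 1.2*Rs``.
    """
    if neck_radius >= sac_radius:
        raise ValidationError("geometric overlap impossible: neck radius must be < sac radius")
    if pipe_length is None:
        pipe_length = 10 * pipe_radius
    rng = np.random.default_rng(seed)
    pipe = make_pipe_mesh(pipe_radius, pipe_length, resolution)
    b = float(np.sqrt(sac_radius**2 - neck_radius**2))
    center = np.array([pipe_length / 2, pipe_radius + b, 0.0])
    h = 2 * sac_radius / resolution
    cap_pts, cap_tets = _cap_mesh(center, sac_radius, pipe_radius, neck_radius, h, rng)
    n_pipe_pts = pipe.n_nodes
    pts = np.vstack([pipe.points, cap_pts])
    pipe_tets = pipe.cells[0][1]
    mesh = VolumeMesh(
        pts,
        [("tetra", pipe_tets), ("tetra", cap_tets + n_pipe_pts)],
        meta={"kind": "aneurysm_pipe", "pipe_radius": pipe_radius,
              "pipe_length": pipe_length, "axis": "x",
              "sac_radius": sac_radius, "neck_radius": neck_radius,
              "sac_center": center.tolist()},
    )
    sac_mask = np.zeros(mesh.n_cells, dtype=bool)
    sac_mask[len(pipe_tets):] = True

    x1 = center[0] - 1.2 * sac_radius
    x2 = center[0] + 1.2 * sac_radius
    if x1 <= 0 or x2 >= pipe_length:
        raise ValidationError("pipe too short to hold the sac between segment planes")
    plane1 = PlaneSpec((x1, 0.0, 0.0), (1.0, 0.0, 0.0), "segment-boundary")
    plane2 = PlaneSpec((x2, 0.0, 0.0), (1.0, 0.0, 0.0), "segment-boundary")
    # ground-truth labels straight from geometry: sac cells belong to the
    # aneurysm part; pipe cells by centroid x position
    cx_cells = mesh.cell_centroids()[:, 0]
    gt = np.ones(mesh.n_cells, dtype=np.intp)
    gt[(~sac_mask) & (cx_cells < x1)] = 0
    gt[(~sac_mask) & (cx_cells >= x2)] = 2

    planes = {
        "C": PlaneSpec((center[0], pipe_radius, 0.0), (0.0, 1.0, 0.0), "C"),  # neck plane
        "B": PlaneSpec((center[0], 0.0, 0.0), (1.0, 0.0, 0.0), "B"),  # flow-normal
        "A": PlaneSpec(tuple(center), (0.0, 0.0, 1.0), "A"),
    }
    if vortex_strength is None:
        vortex_strength = 2 * mean_velocity / sac_radius
    return AneurysmFixture(
        mesh=mesh,
        non_aneurysm_mesh=pipe,
        pipe_radius=pipe_radius,
        pipe_length=pipe_length,
        sac_radius=sac_radius,
        neck_radius=neck_radius,
        sac_center=center,
        mean_velocity=mean_velocity,
        vortex_strength=vortex_strength,
        sac_cell_mask=sac_mask,
        segment_ids=gt,
        boundary_planes=(plane1, plane2),
        planes=planes,
    )


def sac_dp_quadrature(
    fixture: AneurysmFixture,
    props: FluidProperties = BLOOD,
    scale: float = 1.0,
    n_r: int = 48,
    n_t: int = 48,
    n_phi: int = 64,
) -> float:
    """Brute-force oracle: integrate the analytic DF over the exact sac region.

    Spherical coordinates about the sac centre with polar axis -y; the region
    {rho <= Rs, rho*cos(theta) <= b} is covered exactly by splitting the
    radial interval at rho = b, Gauss–Legendre in rho and cos(theta), uniform
    (spectrally accurate) trapezoid in phi.  No geometric discretization error
    — only smooth-integrand quadrature error, negligible at these orders.
    """
    Rs = fixture.sac_radius
    b = float(fixture.sac_center[1] - fixture.pipe_radius)
    mu = props.dynamic_viscosity
    gr, gw = np.polynomial.legendre.leggauss(n_r)
    tr, tw = np.polynomial.legendre.leggauss(n_t)
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    wphi = 2 * np.pi / n_phi
    total = 0.0
    for lo, hi in ((0.0, b), (b, Rs)):
        if hi <= lo:
            continue
        rho = 0.5 * (hi - lo) * gr + 0.5 * (hi + lo)
        wr = 0.5 * (hi - lo) * gw
        for r_k, w_k in zip(rho, wr):
            tmax = min(1.0, b / r_k) if r_k > 0 else 1.0
            t = 0.5 * (tmax + 1.0) * tr + 0.5 * (tmax - 1.0)
            wt = 0.5 * (tmax + 1.0) * tw
            st = np.sqrt(np.clip(1 - t**2, 0, None))
            # polar axis is -y: y = cy - rho*t
            pts = np.empty((len(t) * n_phi, 3))
            pts[:, 0] = fixture.sac_center[0] + r_k * (st[:, None] * np.cos(phis)[None, :]).ravel()
            pts[:, 1] = fixture.sac_center[1] - r_k * np.repeat(t, n_phi)
            pts[:, 2] = fixture.sac_center[2] + r_k * (st[:, None] * np.sin(phis)[None, :]).ravel()
            G = fixture.gradient(pts, scale)
            df = (
                2 * mu * (G[:, 0, 0] ** 2 + G[:, 1, 1] ** 2 + G[:, 2, 2] ** 2)
                + mu * (
                    (G[:, 1, 0] + G[:, 0, 1]) ** 2
                    + (G[:, 2, 1] + G[:, 1, 2]) ** 2
                    + (G[:, 0, 2] + G[:, 2, 0]) ** 2
                )
            )
            total += w_k * r_k**2 * float(np.sum(df.reshape(len(t), n_phi) * wt[:, None]) * wphi)
    return total
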