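"""Bernoulli inlet–outlet energy balance: the comparator to the DF method.

EL_be integrates, over n cardiac cycles,

    m_dot * [ (V_in^2 - V_out^2)/2 + (P_in - P_out)/rho ]

between an inlet cross-section and one or more outlet cross-sections, then
divides by n.  For steady fully developed pipe flow the velocity heads cancel
and EL_be = m_dot*dp/rho = 8*pi*mu*Vbar^2*L — identical to the closed-form
dissipation power, which is the basis of the method-equivalence check.

``V`` is by default the area-averaged velocity magnitude on the section;
the kinetic-energy-flux alternative (which differs by a profile factor, 2x
for a parabolic profile) is selectable via ``kinetic="energy_flux"``.
``P`` is the area-averaged static pressure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, cKDTree

from .core import BLOOD, FieldSnapshot, FluidProperties, ValidationError, VolumeMesh

__all__ = [
    "CrossSection",
    "CrossSectionSummary",
    "MethodComparison",
    "MassBalanceWarning",
    "make_disk_section",
    "FieldInterpolator",
    "cross_section_summary",
    "energy_loss_be",
    "aneurysm_el_be",
    "compare_methods",
]


class MassBalanceWarning(UserWarning):
    """Inlet and outlet mass flows disagree beyond tolerance."""


@dataclass
class CrossSection:
    """Planar triangulated section with a downstream-pointing unit normal."""

    points: np.ndarray  # (p, 3)
    triangles: np.ndarray  # (t, 3)
    normal: np.ndarray  # unit 3-vector

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, float)
        self.triangles = np.ascontiguousarray(self.triangles, np.intp)
        self.normal = np.asarray(self.normal, float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1) > 1e-9:
            raise ValidationError("section normal must be a unit vector")

    def triangle_areas(self) -> np.ndarray:
        a = self.points[self.triangles[:, 0]]
        b = self.points[self.triangles[:, 1]]
        c = self.points[self.triangles[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @property
    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def flipped(self) -> "CrossSection":
        return CrossSection(self.points, self.triangles, -self.normal)


def make_disk_section(center, normal, radius: float, resolution: int = 16) -> CrossSection:
    """Triangulated disk of given radius, oriented by ``normal``."""
    from .synthetic import _disk_points  # local spiderweb layout

    if radius <= 0:
        raise ValidationError("section radius must be positive")
    n = np.asarray(normal, float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValidationError("section normal must be nonzero")
    n = n / nn
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    disk = _disk_points(radius, max(4, resolution // 2))
    tris = Delaunay(disk).simplices
    pts = np.asarray(center, float) + disk[:, :1] * e1 + disk[:, 1:] * e2
    return CrossSection(pts, tris, n)


class FieldInterpolator:
    """Linear (Delaunay) interpolation of nodal fields with nearest fallback.

    One instance per mesh amortises the triangulation over the whole series.
    """

    def __init__(self, mesh: VolumeMesh):
        self.mesh = mesh
        self.tree = cKDTree(mesh.points)
        self._tri = Delaunay(mesh.points)

    def __call__(self, values: np.ndarray, pts: np.ndarray) -> np.ndarray:
        values = np.asarray(values, float)
        interp = LinearNDInterpolator(self._tri, values)
        out = interp(pts)
        bad = np.isnan(out) if out.ndim == 1 else np.isnan(out).any(axis=1)
        if bad.any():
            _, idx = self.tree.query(np.asarray(pts)[bad])
            out[bad] = values[idx]
        return out


@dataclass
class CrossSectionSummary:
    """Per-instant integrals on one cross-section."""

    area: float  # m^2
    mass_flow: float  # kg/s, signed by the section normal
    mean_velocity: float  # m/s, area-averaged |u|
    mean_pressure: float  # Pa, area-averaged static pressure
    time: float  # s
    ke_per_mass: float = 0.0  # J/kg, kinetic-energy flux / mass flow

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValidationError("section area must be positive")
        if not np.isfinite(self.mass_flow):
            raise ValidationError("mass flow must be finite")


def cross_section_summary(
    section: CrossSection,
    snapshot: FieldSnapshot,
    props: FluidProperties = BLOOD,
    interpolator: FieldInterpolator | None = None,
) -> CrossSectionSummary:
    """Integrate velocity and pressure over a section.

    m_dot = rho * surface integral of u.n; V = area-average of |u|;
    P = area-average of pressure.  Vertex values are interpolated from the
    volume mesh and integrated with the linear (vertex-mean) rule per
    triangle.
    """
    areas = section.triangle_areas()
    total_area = float(areas.sum())
    if total_area <= 0:
        raise ValidationError("zero-area section")
    interp = interpolator or FieldInterpolator(snapshot.mesh)
    vel = interp(snapshot.velocity, section.points)
    prs = interp(snapshot.pressure, section.points)
    tri = section.triangles
    un = vel @ section.normal
    speed = np.linalg.norm(vel, axis=1)

    def tri_integral(nodal: np.ndarray) -> float:
        return float(np.sum(nodal[tri].mean(axis=1) * areas))

    flux = tri_integral(un)  # volumetric flow, m^3/s
    mdot = props.density * flux
    ke_flux = 0.5 * props.density * tri_integral(speed**2 * un)  # W
    return CrossSectionSummary(
        area=total_area,
        mass_flow=mdot,
        mean_velocity=tri_integral(speed) / total_area,
        mean_pressure=tri_integral(prs) / total_area,
        time=snapshot.time,
        ke_per_mass=ke_flux / mdot if mdot != 0 else 0.0,
    )


def _as_outlet_list(outlets):
    if outlets and isinstance(outlets[0], CrossSectionSummary):
        return [list(outlets)]
    return [list(o) for o in outlets]


def energy_loss_be(
    inlet,
    outlets,
    props: FluidProperties = BLOOD,
    period: float = 0.8,
    n_cycles: int = 1,
    mass_balance_tol: float = 0.02,
    kinetic: str = "mean_velocity",
) -> float:
    """EL_be (W) from per-instant section summaries over n cycles.

    ``inlet`` is a time-ordered list of ``CrossSectionSummary``; ``outlets``
    is one such list or a list of them.  With a single outlet the inlet mass
    flow multiplies the bracket; with several outlets each outlet's bracket is
    weighted by that outlet's own mass flow and summed (single-inlet energy
    bookkeeping).  A mass imbalance beyond ``mass_balance_tol`` raises a
    ``MassBalanceWarning``; time grids must match exactly.
    """
    if kinetic not in ("mean_velocity", "energy_flux"):
        raise ValidationError(f"unknown kinetic option {kinetic!r}")
    inlet = list(inlet)
    outlet_lists = _as_outlet_list(outlets)
    t = np.array([s.time for s in inlet])
    for ol in outlet_lists:
        to = np.array([s.time for s in ol])
        if to.shape != t.shape or not np.allclose(to, t, rtol=0, atol=1e-9):
            raise ValidationError("inlet/outlet time grids do not match")
    if len(t) < 2:
        raise ValidationError("need at least two time samples")
    mdot_in = np.array([s.mass_flow for s in inlet])
    mdot_out = np.sum([[s.mass_flow for s in ol] for ol in outlet_lists], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        imbalance = np.max(np.abs(np.where(mdot_in != 0, (mdot_out - mdot_in) / mdot_in, 0.0)))
    if imbalance > mass_balance_tol:
        warnings.warn(
            f"mass imbalance {imbalance:.1%} exceeds tolerance {mass_balance_tol:.1%}",
            MassBalanceWarning,
            stacklevel=2,
        )

    def head(s: CrossSectionSummary) -> float:
        if kinetic == "energy_flux":
            return s.ke_per_mass
        return 0.5 * s.mean_velocity**2

    single = len(outlet_lists) == 1
    integrand = np.zeros(len(t))
    for k, s_in in enumerate(inlet):
        acc = 0.0
        for ol in outlet_lists:
            s_out = ol[k]
            mdot = s_in.mass_flow if single else s_out.mass_flow
            acc += mdot * ((head(s_in) - head(s_out)) + (s_in.mean_pressure - s_out.mean_pressure) / props.density)
        integrand[k] = acc
    span = t[-1] - t[0]
    step = float(np.median(np.diff(t)))
    if abs(span - n_cycles * period) > step * (1 + 1e-9):
        raise ValidationError("summary span does not cover n*period within one step")
    return float(np.trapezoid(integrand, t) / (n_cycles * period))


def aneurysm_el_be(el_with: float, el_without: float) -> float:
    """Difference-based sac energy loss: EL_be(with aneurysm) - EL_be(without).

    Signed: a sac that streamlines the flow can yield a negative value.
    """
    return float(el_with) - float(el_without)


@dataclass
class MethodComparison:
    """Whole-domain and sac-level agreement between the two EL methods."""

    el_df: float
    el_be: float
    relative_difference: float
    sac_el_df: float | None = None
    sac_el_be: float | None = None
    sac_relative_difference: float | None = None
    sac_discrepant: bool = False


def compare_methods(
    el_df: float,
    el_be: float,
    sac_el_df: float | None = None,
    sac_el_be: float | None = None,
) -> MethodComparison:
    """Relative differences |EL_be - EL_df| / EL_be, whole-domain and sac level.

    The sac comparison is flagged discrepant when it exceeds the whole-domain
    disagreement — the signature of the difference-based sac estimate missing
    flow-field changes caused by the aneurysm.
    """
    for v in (el_df, el_be):
        if not np.isfinite(v):
            raise ValidationError("energy losses must be finite")
    if el_be <= 0:
        raise ValidationError("el_be must be positive for a relative comparison")
    rel = abs(el_be - el_df) / el_be
    comp = MethodComparison(el_df=el_df, el_be=el_be, relative_difference=rel)
    if sac_el_df is not None and sac_el_be is not None:
        denom = abs(sac_el_be) if sac_el_be != 0 else abs(sac_el_df)
        sac_rel = abs(sac_el_be - sac_el_df) / denom if denom > 0 else 0.0
        comp.sac_el_df = sac_el_df
        comp.sac_el_be = sac_el_be
        comp.sac_relative_difference = sac_rel
        comp.sac_discrepant = sac_rel > rel
    return comp
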