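# Methods

## Model

`dissipel` treats blood as an incompressible Newtonian fluid in laminar flow
with constant density ρ and dynamic viscosity μ (defaults 1060 kg/m³ and
0.004 Pa·s), inside rigid, no-slip walls. Under these assumptions the rate of
irreversible conversion of mechanical energy into heat per unit volume is the
dissipation function

DF = 2μ(Gxx² + Gyy² + Gzz²) + μ[(Gyx+Gxy)² + (Gzy+Gyz)² + (Gxz+Gzx)²],

where G is the velocity-gradient tensor, G(i,j) = ∂u_i/∂x_j. Only the
symmetric (strain) part of G contributes: rigid rotation dissipates nothing,
and DF ≥ 0 always. The compressible bulk term and any temperature coupling
are outside the model; a non-Newtonian μ(γ̇) is likewise out of scope — DF in
this form holds for Newtonian fluids only.

The two derived quantities are the dissipation power
DP(t) = ∭_CV DF dv over a user-chosen control volume, and the
cycle-averaged energy loss EL_df = (1/nT)∫ DP dt over n cardiac cycles of
period T. EL is reported in W (average power); the per-cycle energy in J is
EL × T. Normalising by nT (rather than by n alone) makes a constant DP map
to itself and keeps EL_df and the Bernoulli-based EL_be on a common scale.

The comparator EL_be = (1/nT)∫ ṁ[(V_in²−V_out²)/2 + (P_in−P_out)/ρ]dt uses
cross-section integrals: ṁ = ρ∮u·n dA, V the area-averaged velocity
magnitude, P the area-averaged static pressure. V is not uniquely defined by
the balance; the kinetic-energy-flux alternative (which differs by the
profile factor — exactly 2× for a parabolic profile) is available via
`kinetic="energy_flux"`. With several outlets, each outlet's bracket is
weighted by that outlet's own ṁ (single-inlet energy bookkeeping); with one
outlet the inlet ṁ multiplies the bracket. Gravity head and compliant
outlets are not modelled.

## Discretisation

**Gradients.** Three schemes, selectable as `wlsq`, `green_gauss`,
`structured`:

* *wlsq* (default on unstructured meshes): per node, a weighted
  least-squares fit of a linear field over the edge-connected 1-ring, with
  inverse-distance weights. Exact for globally linear fields; wall nodes get
  their one-sided stencil implicitly through interior neighbours. The
  neighbourhood is exactly the 1-ring (no k-ring growth) so the operator is
  local and deterministic; a rank-deficient neighbourhood (all neighbours
  coplanar, only possible on degenerate meshes) is a hard error naming the
  node.
* *green_gauss*: exact linear-shape-function gradients per tetrahedron,
  volume-averaged to nodes; retained as an independent cross-check.
* *structured*: `numpy.gradient` on rectilinear grids — 2nd-order central
  in the interior, 2nd-order one-sided at boundaries.

**Quadrature.** DP uses cell-wise midpoint quadrature: the mean of a cell's
nodal DF values times its volume (hexahedra are decomposed into six
tetrahedra around the 0–6 diagonal, which conserves volume exactly for
planar faces). This is exact for constant DF and converges at order ≈ 1.9 on
the Poiseuille benchmark. Because DF is quadratic in gradients, discrete DP
systematically underestimates near walls; the mitigation is refinement
(measured on the steady pipe: −9.0% at 8 cells across the diameter, −2.5% at
16, −1.1% at 24, −0.66% at 32). The default validation mesh therefore uses
24 cells across the diameter.

For fields that are only C⁰ at a boundary — the prescribed sac vortex below
vanishes on the sac wall with a kink — nodal DF sampling misses the
near-wall shear and converges only at first order. `cell_dissipation_power`
integrates DF of the exact per-tet linear gradient instead (one DF value per
sub-tetrahedron), which restores the expected accuracy (+2.4% against the
sac oracle at resolution 16 versus −15% for the nodal route). The nodal
route remains the default pipeline; the cell route is used for sac-level
integrals.

**Time integration.** Composite trapezoid on the snapshot grid over
[t0, t0+nT], t0 defaulting to the first snapshot. On the default cardiac
sampling (T = 0.8 s, step 0.01 s, 81 snapshots per cycle) the trapezoid
error on smooth periodic integrands is far below 0.1%.

**Cross-sections.** Sections are triangulated disks; nodal fields are
interpolated onto section vertices by Delaunay-based linear interpolation
with nearest-node fallback on the hull, then integrated with the
vertex-mean rule per triangle. A mass imbalance |Σṁ_out − ṁ_in|/ṁ_in above
a 2% tolerance raises a `MassBalanceWarning` rather than an error, since
interpolation error alone can trip it on coarse meshes.

**Segmentation.** Cells are assigned whole to inlet/aneurysm/outlet by the
signed side of their centroid relative to two downstream-oriented planes.
This is deterministic and exactly volume-conserving at the cost of a
one-cell-layer uncertainty in per-segment DP near each boundary plane. The
neck and boundary planes are explicit inputs; no automatic neck detection is
attempted.

## Units

Strictly SI: m, s, kg, Pa, W. CFD exports in millimetres must be read with
`length_scale: 1e-3`; nothing rescales silently. Velocity-gradient tensors
are s⁻¹, DF W/m³, DP and EL W.

## Synthetic fixtures and what they show

The generator produces the study conditions used throughout: blood
properties as above, a parent vessel of radius 2 mm, pipe length 20 mm,
mean inlet velocity 0.3 m/s, cardiac period 0.8 s sampled at 0.01 s.

* **Steady Poiseuille pipe** — closed forms DP = 8πμV̄²L and
  Δp = 8μLV̄/R², with EL_be = ṁΔp/ρ equal to DP analytically. The tet pipe
  mesh is an extruded Delaunay-triangulated spiderweb disk; its cross-section
  is an inscribed polygon, so the volume is ~0.3% low at 16 cells across the
  diameter, converging quadratically.
* **Quasi-steady pulsatile series** — a steady profile rescaled by
  V̄(t) = V₀(1 + a·sin 2πt/T). For a = 0.5 the cycle mean of V̄² is
  1.125·V₀², so EL_df = 1.125 × the steady value; since DP scales exactly
  quadratically with velocity on any fixed mesh, this ratio is
  mesh-independent. A measured patient waveform can be substituted as a
  tabulated table; the default sinusoid is a unimodal stand-in (systolic
  rise, diastolic decay). Being quasi-steady, the series has **no** phase lag
  between inlet velocity and DP — real pulsatile flow shows hysteresis from
  unsteady inertia, which a prescribed-field generator cannot reproduce, so
  passing tests say nothing about that effect.
* **Null/exact fixtures** — uniform flow and rigid rotation (DF ≡ 0), planar
  Couette (DF ≡ μ(U/h)², 40 W/m³ at U = 0.1 m/s, h = 1 mm).
* **Idealized sidewall aneurysm** — a spherical sac of radius Rs mounted on
  the pipe's tangent plane, centre at y = Rp + √(Rs²−Rn²) so the cut disk
  has exactly the neck radius Rn; the sac region {|p−c| ≤ Rs, y ≥ Rp} is
  convex and provably disjoint from the pipe interior, so their meshes
  concatenate without double counting. The sac carries a prescribed swirl
  u = A(x̂×d)·e·g with envelope e = 1−|d|²/Rs² (zero on the sphere) and
  g = (y−Rp)/Rs (zero on the neck plane), so the blended field is continuous
  everywhere and no-slip on all walls. It is *not* a Navier–Stokes solution;
  its only role is to exercise the pipeline on a field with known
  dissipation. The default swirl strength A = 2V̄/Rs gives sac dissipation
  of the same order as the parent vessel's. The brute-force oracle for the
  sac DP is Gauss–Legendre quadrature in spherical coordinates about the sac
  centre (exact geometry, spectrally accurate in the smooth integrand),
  cross-checked against Monte Carlo during development and against its own
  refinement in the tests.

The fixture also demonstrates why difference-based sac estimates mislead:
the prescribed parent-vessel flow is identical with and without the sac, so
EL_beAN = EL_be(with) − EL_be(without) ≈ 0 while direct integration over the
sac gives EL_dfAN > 0. Real aneurysms change the bypass flow too, but the
qualitative failure mode — the differencing is blind to dissipation that
does not alter the inlet/outlet balance — is the same.

## Numerical choices and degenerate inputs

* Degenerate (zero/negative-volume) cells are reported by index at
  validation time; series validation reports non-monotone times, mesh
  mismatches and non-finite fields without aborting, except for an empty
  series which is a hard error.
* Determinism: all randomness (lattice jitter in the sac mesher, waveform
  perturbations) flows from an explicit integer seed; identical
  configuration and inputs produce byte-identical CSV reports (9 significant
  digits, fixed row order).
* The sac mesher seeds a jittered lattice plus Fibonacci sphere-surface,
  neck-rim and neck-disk points and tetrahedralises them with Delaunay;
  exact-zero-volume hull slivers are dropped. Jitter (5% of the spacing)
  exists solely to avoid cospherical degeneracies of a regular lattice.
* Cells cut by a segmentation plane are not split; centroid-side assignment
  was chosen over cell cutting for determinism and exact volume
  conservation.

## Known limitations

* Rigid walls, Newtonian rheology, laminar flow — inherited model
  assumptions, not checked from data.
* The nodal DP quadrature under-reads near walls at coarse resolution; use
  ≥ 24 cells across a vessel diameter, or the cell route where the field has
  boundary kinks.
* Prism/wedge boundary-layer cells must be pre-split to tetrahedra by the
  exporter; only tetrahedra and hexahedra are accepted.
* Only ASCII XML VTU files are read/written; binary/appended VTU and legacy
  VTK are not supported.
* The Bernoulli comparator's V is ambiguous in principle; both supported
  definitions are exposed, and comparisons should state which was used.
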