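import numpy as np
import pytest

import dissipel as dl
from conftest import PIPE_L, PIPE_R, VBAR


class TestPipeMesh:
    def test_volume_close_to_cylinder(self, pipe16):
        exact = np.pi * PIPE_R**2 * PIPE_L
        assert pipe16.total_volume == pytest.approx(exact, rel=0.02)

    def test_refinement_shrinks_volume_error(self):
        exact = np.pi * PIPE_R**2 * PIPE_L
        e8 = abs(dl.make_pipe_mesh(PIPE_R, PIPE_L, 8).total_volume - exact)
        e16 = abs(dl.make_pipe_mesh(PIPE_R, PIPE_L, 16).total_volume - exact)
        assert e16 <= e8 / 2

    def test_too_coarse_rejected(self):
        with pytest.raises(dl.ValidationError, match=">= 8"):
            dl.make_pipe_mesh(PIPE_R, PIPE_L, 4)

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(dl.ValidationError, match="positive"):
            dl.make_pipe_mesh(-1e-3, PIPE_L, 16)


class TestPoiseuilleSnapshot:
    def test_centerline_speed_twice_mean(self, pipe16):
        snap = dl.poiseuille_snapshot(pipe16, VBAR)
        axis = np.hypot(pipe16.points[:, 1], pipe16.points[:, 2]) < 1e-12
        assert np.allclose(snap.velocity[axis, 0], 2 * VBAR, rtol=1e-12)

    def test_no_slip_at_wall(self, pipe16):
        snap = dl.poiseuille_snapshot(pipe16, VBAR)
        r = np.hypot(pipe16.points[:, 1], pipe16.points[:, 2])
        wall = r >= PIPE_R * (1 - 1e-9)
        assert wall.any()
        assert np.allclose(snap.velocity[wall], 0.0, atol=1e-12)

    def test_hagen_poiseuille_pressure_drop(self, pipe16, props):
        # dp = 8*mu*L*Vbar/R^2 = 48 Pa for the canonical conditions
        snap = dl.poiseuille_snapshot(pipe16, VBAR, props)
        inlet = snap.pressure[pipe16.points[:, 0] < 1e-12]
        outlet = snap.pressure[pipe16.points[:, 0] > PIPE_L - 1e-12]
        assert inlet.mean() - outlet.mean() == pytest.approx(48.0, rel=1e-12)

    def test_requires_pipe_mesh(self, small_box):
        with pytest.raises(dl.ValidationError, match="pipe mesh"):
            dl.poiseuille_snapshot(small_box, VBAR)


class TestWaveform:
    def test_default_cardiac_sampling_gives_81_snapshots(self):
        mesh = dl.make_pipe_mesh(PIPE_R, 2e-3, 8)
        series = dl.pulsatile_series(mesh, dl.WaveformSpec())
        assert len(series.snapshots) == 81
        assert dl.validate_series(series) == []

    def test_constant_waveform_identical_snapshots(self):
        mesh = dl.make_pipe_mesh(PIPE_R, 2e-3, 8)
        wf = dl.WaveformSpec(shape="constant", period=0.8, step=0.2)
        series = dl.pulsatile_series(mesh, wf)
        for snap in series.snapshots[1:]:
            assert np.array_equal(snap.velocity, series.snapshots[0].velocity)

    def test_step_must_divide_period(self):
        with pytest.raises(dl.ValidationError, match="divide"):
            dl.WaveformSpec(period=0.8, step=0.03)

    def test_amplitude_must_keep_velocity_positive(self):
        with pytest.raises(dl.ValidationError, match="amplitude"):
            dl.WaveformSpec(amplitude=1.0)


class TestNullAndExactFixtures:
    def test_couette_df_everywhere(self, small_box, props):
        """DF = mu*(U/h)^2 = 40 W/m^3 for U=0.1 m/s across h=1 mm."""
        snap = dl.couette_snapshot(small_box, 0.1)
        df = dl.dissipation_function(dl.compute_gradients(snap, "wlsq"), props)
        assert df.values == pytest.approx(np.full(small_box.n_nodes, 40.0), rel=0.005)

    def test_uniform_flow_dissipates_nothing(self, small_box, props):
        dp = dl.dissipation_power(
            dl.dissipation_function(dl.uniform_gradient(small_box), props))
        assert dp == 0.0

    def test_rigid_rotation_dissipates_nothing(self, small_box, props):
        couette_dp = 40.0 * small_box.total_volume
        ga = dl.rigid_rotation_gradient(small_box, 10.0)
        assert dl.dissipation_power(dl.dissipation_function(ga, props)) <= 1e-12 * couette_dp
        snap = dl.rigid_rotation_snapshot(small_box, 10.0)
        g = dl.compute_gradients(snap, "wlsq")
        assert dl.dissipation_power(dl.dissipation_function(g, props)) <= 0.01 * couette_dp


class TestAneurysmFixture:
    def test_determinism_and_seed_sensitivity(self):
        a = dl.idealized_aneurysm_fixture(resolution=8, seed=5)
        b = dl.idealized_aneurysm_fixture(resolution=8, seed=5)
        c = dl.idealized_aneurysm_fixture(resolution=8, seed=6)
        assert np.array_equal(a.mesh.points, b.mesh.points)
        assert a.mesh.points.shape != c.mesh.points.shape or not np.array_equal(
            a.mesh.points, c.mesh.points)

    def test_neck_wider_than_sac_rejected(self):
        with pytest.raises(dl.ValidationError, match="overlap impossible"):
            dl.idealized_aneurysm_fixture(sac_radius=1e-3, neck_radius=2e-3)

    def test_no_slip_on_sac_surface(self, aneurysm16):
        fx = aneurysm16
        d = np.linalg.norm(fx.mesh.points - fx.sac_center, axis=1)
        on_sphere = np.abs(d - fx.sac_radius) < 1e-12 * fx.sac_radius
        assert on_sphere.any()
        assert np.allclose(fx.velocity(fx.mesh.points[on_sphere]), 0.0, atol=1e-12)

    def test_field_gradient_consistency(self, aneurysm16):
        """Analytic gradient matches central differences of the velocity."""
        fx = aneurysm16
        rng = np.random.default_rng(0)
        pts = fx.sac_center + rng.uniform(-0.5, 0.5, (200, 3)) * fx.sac_radius
        inside = (np.linalg.norm(pts - fx.sac_center, axis=1) < 0.9 * fx.sac_radius) & (
            pts[:, 1] > fx.pipe_radius + 0.05 * fx.sac_radius)
        pts = pts[inside]
        eps = 1e-8
        G_fd = np.empty((len(pts), 3, 3))
        for j in range(3):
            dv = np.zeros(3)
            dv[j] = eps
            G_fd[:, :, j] = (fx.velocity(pts + dv) - fx.velocity(pts - dv)) / (2 * eps)
        assert np.allclose(G_fd, fx.gradient(pts), atol=1e-5 * np.abs(G_fd).max())

    def test_sac_dissipation_positive_and_additive(self, aneurysm16, props):
        fx = aneurysm16
        snap = fx.snapshot()
        g = dl.gradient_unstructured(fx.mesh, snap)
        df = dl.dissipation_function(g, props)
        dp_sac = dl.dissipation_power(df, fx.mesh, fx.sac_cell_mask)
        dp_all = dl.dissipation_power(df)
        dp_parent = dl.dissipation_power(df, fx.mesh, ~fx.sac_cell_mask)
        assert dp_sac > 0
        assert dp_all >= dp_parent
        assert dp_all == pytest.approx(dp_sac + dp_parent, rel=1e-12)

    def test_sac_dp_matches_brute_force_oracle(self, aneurysm16, props):
        """Cell-route DP over the sac vs exact-geometry quadrature (<=3%)."""
        fx = aneurysm16
        dp = dl.cell_dissipation_power(fx.snapshot(), props, fx.sac_cell_mask)
        oracle = dl.sac_dp_quadrature(fx, props)
        assert dp == pytest.approx(oracle, rel=0.03)

    def test_oracle_quadrature_is_converged(self, aneurysm16):
        coarse = dl.sac_dp_quadrature(aneurysm16, n_r=24, n_t=24, n_phi=32)
        fine = dl.sac_dp_quadrature(aneurysm16, n_r=48, n_t=48, n_phi=64)
        assert coarse == pytest.approx(fine, rel=1e-3)
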