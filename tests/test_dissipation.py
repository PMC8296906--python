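import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dissipel as dl
from conftest import PIPE_L, PIPE_R, VBAR, steady_power_series


def field_from_tensor(mesh, tensor):
    t = np.broadcast_to(np.asarray(tensor, float), (mesh.n_nodes, 3, 3))
    return dl.GradientField(mesh, t.copy())


class TestDissipationFunction:
    # (tensor G[i][j] = d u_i / d x_j, expected DF at mu = 0.004)
    CASES = [
        (np.zeros((3, 3)), 0.0, "zero tensor"),
        ([[0, 100, 0], [0, 0, 0], [0, 0, 0]], 40.0, "simple shear du/dy=100"),
        ([[0, -10, 0], [10, 0, 0], [0, 0, 0]], 0.0, "rigid rotation"),
        # hand evaluation: 2mu(1+9+16) + mu(0+2)^2 = 0.208 + 0.016
        ([[1, 2, 0], [0, 3, 0], [0, 0, -4]], 0.224, "full tensor"),
    ]

    @pytest.mark.parametrize("tensor,expected,_id", CASES, ids=[c[2] for c in CASES])
    def test_known_tensors(self, small_box, props, tensor, expected, _id):
        df = dl.dissipation_function(field_from_tensor(small_box, tensor), props)
        assert df.values == pytest.approx(np.full(small_box.n_nodes, expected), abs=1e-13)

    def test_non_finite_tensor_rejected(self, small_box, props):
        g = field_from_tensor(small_box, np.eye(3))
        g.tensors[5, 0, 0] = np.nan
        with pytest.raises(dl.ValidationError, match="node 5"):
            dl.dissipation_function(g, props)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_for_random_tensors(self, small_box, props, seed):
        rng = np.random.default_rng(seed)
        g = dl.GradientField(small_box, rng.normal(scale=100, size=(small_box.n_nodes, 3, 3)))
        assert np.all(dl.dissipation_function(g, props).values >= 0)


class TestDissipationPower:
    def test_constant_df_gives_c_times_volume(self, pipe16):
        df = dl.DissipationField(pipe16, np.full(pipe16.n_nodes, 7.5))
        assert dl.dissipation_power(df) == pytest.approx(7.5 * pipe16.total_volume, rel=1e-12)

    def test_quadratic_velocity_scaling(self, pipe16, props):
        snap = dl.poiseuille_snapshot(pipe16, VBAR)
        scaled = dl.FieldSnapshot(pipe16, 0.0, 3.0 * snap.velocity, snap.pressure)
        dp1 = dl.dissipation_power(
            dl.dissipation_function(dl.gradient_unstructured(pipe16, snap), props))
        dp9 = dl.dissipation_power(
            dl.dissipation_function(dl.gradient_unstructured(pipe16, scaled), props))
        assert dp9 == pytest.approx(9.0 * dp1, rel=1e-10)

    def test_empty_region_rejected(self, pipe16):
        df = dl.DissipationField(pipe16, np.ones(pipe16.n_nodes))
        with pytest.raises(dl.ValidationError, match="empty"):
            dl.dissipation_power(df, pipe16, np.zeros(pipe16.n_cells, dtype=bool))

    def test_poiseuille_matches_closed_form(self, pipe24_dp, props):
        """DP -> 8*pi*mu*Vbar^2*L on the default validation mesh (<=2%)."""
        oracle = dl.analytic_poiseuille_dp(props, VBAR, PIPE_L)
        assert pipe24_dp == pytest.approx(oracle, rel=0.02)

    def test_rotation_insensitivity(self, pipe16, props):
        """Adding a rigid rotation to a snapshot leaves DF (hence DP) unchanged."""
        snap = dl.poiseuille_snapshot(pipe16, VBAR)
        rot = dl.rigid_rotation_snapshot(pipe16, omega=50.0)
        combined = dl.FieldSnapshot(pipe16, 0.0, snap.velocity + rot.velocity, snap.pressure)
        dp0 = dl.dissipation_power(
            dl.dissipation_function(dl.gradient_unstructured(pipe16, snap), props))
        dp1 = dl.dissipation_power(
            dl.dissipation_function(dl.gradient_unstructured(pipe16, combined), props))
        assert dp1 == pytest.approx(dp0, rel=1e-9)


class TestPowerSeries:
    def test_steady_series_constant_dp(self, props):
        mesh = dl.make_pipe_mesh(PIPE_R, 4e-3, 8)
        wf = dl.WaveformSpec(base_velocity=VBAR, shape="constant", period=0.8, step=0.2)
        ps = dl.dissipation_power_series(dl.pulsatile_series(mesh, wf), props)
        assert np.allclose(ps.dp_values, ps.dp_values[0], rtol=1e-12)

    def test_quasisteady_dp_tracks_waveform_squared(self, props):
        mesh = dl.make_pipe_mesh(PIPE_R, 4e-3, 16)
        wf = dl.WaveformSpec(base_velocity=VBAR, amplitude=0.5, period=0.8, step=0.2)
        series = dl.pulsatile_series(mesh, wf)
        ps = dl.dissipation_power_series(series, props)
        closed = dl.analytic_poiseuille_dp(props, 1.0, 4e-3) * wf.mean_velocity(ps.times) ** 2
        ratios = ps.dp_values / closed
        # one common mesh factor, constant across the cycle
        assert np.allclose(ratios, ratios[0], rtol=1e-10)
        assert ratios[0] == pytest.approx(1.0, rel=0.05)

    def test_empty_series_is_error(self, props):
        with pytest.raises(dl.ValidationError, match="empty"):
            dl.dissipation_power_series(dl.FieldSeries([], period=0.8), props)


class TestEnergyLossDf:
    def test_constant_dp_returns_dp_exactly(self):
        ps = steady_power_series(3.25e-4, n_steps=8)
        assert dl.energy_loss_df(ps, period=0.8) == pytest.approx(3.25e-4, rel=1e-14)

    def test_sinusoid_squared_cycle_average(self):
        """V(t) = V0(1 + 0.5 sin) -> mean of V^2/V0^2 = 1 + 0.5^2/2 = 1.125."""
        t = np.arange(81) * 0.01
        base = 7.0
        dp = base * (1 + 0.5 * np.sin(2 * np.pi * t / 0.8)) ** 2
        el = dl.energy_loss_df(dl.PowerSeries(t, dp), period=0.8)
        assert el == pytest.approx(1.125 * base, rel=1e-3)

    def test_two_identical_cycles_match_one(self):
        t1 = np.arange(81) * 0.01
        dp1 = 2.0 + np.sin(2 * np.pi * t1 / 0.8) ** 2
        t2 = np.arange(161) * 0.01
        dp2 = 2.0 + np.sin(2 * np.pi * t2 / 0.8) ** 2
        el1 = dl.energy_loss_df(dl.PowerSeries(t1, dp1), period=0.8, n_cycles=1)
        el2 = dl.energy_loss_df(dl.PowerSeries(t2, dp2), period=0.8, n_cycles=2)
        assert el2 == pytest.approx(el1, rel=1e-12)

    def test_span_mismatch_rejected(self):
        ps = steady_power_series(1.0, period=0.8, n_steps=4)
        with pytest.raises(dl.ValidationError, match="span"):
            dl.energy_loss_df(ps, period=0.4)
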