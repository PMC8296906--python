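import dataclasses

import numpy as np
import pytest

import dissipel as dl
from conftest import PIPE_L, PIPE_R, VBAR


def summary(mass_flow, velocity, pressure, time=0.0, area=1e-5, ke=None):
    return dl.CrossSectionSummary(
        area=area, mass_flow=mass_flow, mean_velocity=velocity,
        mean_pressure=pressure, time=time,
        ke_per_mass=ke if ke is not None else 0.5 * velocity**2,
    )


def steady(s):
    return [dataclasses.replace(s, time=0.0), dataclasses.replace(s, time=0.8)]


class TestCrossSectionSummary:
    def test_uniform_flow_mass_rate(self, pipe16, props):
        """m_dot = rho*pi*R^2*V for plug flow through a disk section."""
        snap = dl.uniform_snapshot(pipe16, (VBAR, 0, 0))
        sect = dl.make_disk_section((PIPE_L / 2, 0, 0), (1, 0, 0), PIPE_R, 16)
        s = dl.cross_section_summary(sect, snap, props)
        assert s.mass_flow == pytest.approx(1060 * np.pi * PIPE_R**2 * VBAR, rel=0.02)
        assert s.mean_velocity == pytest.approx(VBAR, rel=1e-9)

    def test_poiseuille_area_average_is_vbar(self, pipe24, poiseuille24, props):
        sect = dl.make_disk_section((PIPE_L / 2, 0, 0), (1, 0, 0), PIPE_R, 24)
        s = dl.cross_section_summary(sect, poiseuille24, props)
        assert s.mean_velocity == pytest.approx(VBAR, rel=0.01)
        # parabolic profile: kinetic-energy flux per unit mass = 2 x (V^2/2)
        assert s.ke_per_mass == pytest.approx(VBAR**2, rel=0.02)

    def test_flipped_normal_negates_mass_flow(self, pipe16, props):
        snap = dl.poiseuille_snapshot(pipe16, VBAR)
        sect = dl.make_disk_section((PIPE_L / 2, 0, 0), (1, 0, 0), PIPE_R, 16)
        s1 = dl.cross_section_summary(sect, snap, props)
        s2 = dl.cross_section_summary(sect.flipped(), snap, props)
        assert s2.mass_flow == pytest.approx(-s1.mass_flow, rel=1e-12)
        assert s2.mean_velocity == pytest.approx(s1.mean_velocity, rel=1e-12)
        assert s2.mean_pressure == pytest.approx(s1.mean_pressure, rel=1e-12)

    def test_zero_area_section_rejected(self, pipe16, props):
        pts = np.zeros((3, 3))
        sect = dl.CrossSection(pts, np.array([[0, 1, 2]]), np.array([1.0, 0, 0]))
        with pytest.raises(dl.ValidationError, match="zero-area"):
            dl.cross_section_summary(sect, dl.uniform_snapshot(pipe16), props)


class TestEnergyLossBe:
    def test_steady_poiseuille_closed_form(self, pipe24_sections, props):
        """Velocity heads cancel; EL_be = m_dot*dp/rho = 8*pi*mu*Vbar^2*L."""
        el = dl.energy_loss_be(pipe24_sections["inlet"], pipe24_sections["outlet"],
                               props, period=0.8)
        assert el == pytest.approx(dl.analytic_poiseuille_dp(props, VBAR, PIPE_L), rel=0.02)

    def test_identical_sections_lose_nothing(self, props):
        s = summary(4e-3, 0.3, 100.0)
        assert dl.energy_loss_be(steady(s), steady(s), props, period=0.8) == 0.0

    def test_lossless_contraction(self, props):
        """Bernoulli identity: pressure drop exactly pays the kinetic gain."""
        v_in, v_out = 0.3, 0.6
        p_in = 200.0
        p_out = p_in - props.density * (v_out**2 - v_in**2) / 2
        el = dl.energy_loss_be(steady(summary(4e-3, v_in, p_in)),
                               steady(summary(4e-3, v_out, p_out)), props, period=0.8)
        assert el == pytest.approx(0.0, abs=1e-15)

    def test_global_pressure_offset_invariance(self, props):
        s_in, s_out = summary(4e-3, 0.3, 120.0), summary(4e-3, 0.25, 80.0)
        el0 = dl.energy_loss_be(steady(s_in), steady(s_out), props, period=0.8)
        off = 1.0e4
        el1 = dl.energy_loss_be(
            steady(dataclasses.replace(s_in, mean_pressure=s_in.mean_pressure + off)),
            steady(dataclasses.replace(s_out, mean_pressure=s_out.mean_pressure + off)),
            props, period=0.8)
        assert el1 == pytest.approx(el0, rel=1e-12)

    @pytest.mark.parametrize("imbalance,warns", [(0.05, True), (0.01, False)])
    def test_mass_balance_warning_threshold(self, props, imbalance, warns, recwarn):
        s_in = summary(4e-3, 0.3, 120.0)
        s_out = summary(4e-3 * (1 + imbalance), 0.3, 80.0)
        import warnings as _w
        with _w.catch_warnings(record=True) as rec:
            _w.simplefilter("always")
            dl.energy_loss_be(steady(s_in), steady(s_out), props, period=0.8,
                              mass_balance_tol=0.02)
        seen = any(issubclass(r.category, dl.MassBalanceWarning) for r in rec)
        assert seen == warns

    def test_multi_outlet_uses_outlet_mass_flows(self, props):
        s_in = summary(4e-3, 0.3, 120.0)
        half = summary(2e-3, 0.3, 80.0)
        el_split = dl.energy_loss_be(steady(s_in), [steady(half), steady(half)],
                                     props, period=0.8)
        el_single = dl.energy_loss_be(steady(s_in), steady(summary(4e-3, 0.3, 80.0)),
                                      props, period=0.8)
        assert el_split == pytest.approx(el_single, rel=1e-12)

    def test_time_grid_mismatch_rejected(self, props):
        s = summary(4e-3, 0.3, 100.0)
        bad = [dataclasses.replace(s, time=0.0), dataclasses.replace(s, time=0.7)]
        with pytest.raises(dl.ValidationError, match="time grids"):
            dl.energy_loss_be(steady(s), bad, props, period=0.8)


class TestAneurysmElBe:
    def test_equal_models_give_zero(self):
        assert dl.aneurysm_el_be(1.0e-4, 1.0e-4) == 0.0

    def test_signed_subtraction(self):
        assert dl.aneurysm_el_be(1.2e-4, 1.0e-4) == pytest.approx(2.0e-5)
        assert dl.aneurysm_el_be(1.0e-4, 1.2e-4) == pytest.approx(-2.0e-5)


class TestCompareMethods:
    def test_two_percent_example(self):
        comp = dl.compare_methods(0.98, 1.00)
        assert comp.relative_difference == pytest.approx(0.02)

    def test_equal_inputs_agree(self):
        assert dl.compare_methods(1.0, 1.0).relative_difference == 0.0

    def test_nonpositive_el_be_rejected(self):
        with pytest.raises(dl.ValidationError, match="positive"):
            dl.compare_methods(1.0, 0.0)

    def test_sac_level_discrepancy_flagged(self):
        comp = dl.compare_methods(0.98, 1.00, sac_el_df=0.25, sac_el_be=0.20)
        assert comp.sac_relative_difference == pytest.approx(0.25)
        assert comp.sac_discrepant
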