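"""Freezing model: thermodynamics, nucleation, solidification, full stage runs."""

import numpy as np
import pytest

from lyosim import ModelConfig, Protocol, Ramp, make_case
from lyosim.config import Ambient, InvalidParameterError
from lyosim.freezing import (InfeasibleNucleationError, dH_vap,
                             equilibrium_freezing_point, evaporation_flux,
                             nucleation_jump, nucleation_probability_rhs,
                             precondition_rhs, psat_liquid, simulate_freezing,
                             solidification_geometry, solidification_rhs,
                             visf_rhs)


class TestVaporProperties:
    def test_psat_liquid_at_ice_point(self):
        # must agree with the ~611 Pa triple-point pressure
        assert psat_liquid(273.15) == pytest.approx(610.0, rel=0.005)

    def test_psat_strictly_increasing(self):
        T = np.linspace(250.0, 320.0, 50)
        assert np.all(np.diff(psat_liquid(T)) > 0)

    def test_psat_domain_error(self):
        with pytest.raises(InvalidParameterError):
            psat_liquid(40.0)

    def test_latent_heat_at_boiling_point(self):
        assert float(dH_vap(373.15)) == pytest.approx(2.257e6, rel=1e-12)

    def test_latent_heat_at_ice_point(self):
        # steam-table value ~2.50e6; the Watson scaling gives ~2.54e6
        assert float(dH_vap(273.15)) == pytest.approx(2.54e6, rel=0.005)

    def test_latent_heat_decreasing_to_critical_point(self):
        T = np.linspace(270.0, 640.0, 50)
        h = dH_vap(T)
        assert np.all(np.diff(h) < 0)
        assert float(dH_vap(647.05)) < 1e5


class TestEvaporationFlux:
    A_z = np.pi * 0.024 ** 2 / 4

    def test_dry_chamber_hand_value(self):
        # T = 268 K, 10 kPa total, chamber free of water vapor
        p_sat = float(psat_liquid(268.0))
        x_sat = p_sat * 0.018 / (p_sat * 0.018 + (1e4 - p_sat) * 0.028)
        flux = evaporation_flux(268.0, 1e4, 0.0, 6.34e-3, self.A_z, 0.018, 0.028)
        assert flux == pytest.approx(-6.34e-3 * self.A_z * x_sat, rel=1e-12)
        assert flux < 0

    def test_saturated_interface_caps_at_pure_vapor(self):
        # total pressure below saturation: driving fraction saturates at 1
        flux = evaporation_flux(268.0, 100.0, 0.0, 6.34e-3, self.A_z, 0.018, 0.028)
        assert flux == pytest.approx(-6.34e-3 * self.A_z, rel=1e-12)

    def test_no_driving_force(self):
        p_sat = float(psat_liquid(268.0))
        flux = evaporation_flux(268.0, 1e4, p_sat, 6.34e-3, self.A_z, 0.018, 0.028)
        assert flux == 0.0


class TestPreconditionRhs:
    def test_equilibrium(self, cfg, flat_protocol):
        amb = flat_protocol(0.0)
        assert precondition_rhs(265.0, amb, cfg, cfg.m_w0) == pytest.approx(0.0, abs=1e-15)

    def test_cooling_sign_and_hand_value(self, cfg):
        from lyosim.config import SIGMA
        amb = Ambient(T_b=270.0, T_g=268.0, T_c=272.0, T_u=272.0, p_t=1e5, p_w_c=0.0)
        T = 280.0
        got = precondition_rhs(T, amb, cfg, cfg.m_w0)
        # independent term-by-term evaluation
        A_z = cfg.vial.A_z
        h_fill = cfg.formulation.V_l / A_z
        A_r = np.pi * cfg.vial.d * h_fill
        Q = (5.0 * A_z * (272.0 - T) + 10.0 * A_z * (268.0 - T)
             + 8.0 * A_r * (268.0 - T) + SIGMA * A_r * 0.624 * (272.0 ** 4 - T ** 4))
        C = cfg.m_s * 1204.0 + cfg.m_w0 * 4187.0
        assert got == pytest.approx(Q / C, rel=1e-12)
        assert got < 0

    def test_visf_reduces_to_precondition_without_evaporation(self, cfg):
        amb = Ambient(T_b=270.0, T_g=260.0, T_c=265.0, T_u=265.0, p_t=1e5, p_w_c=0.0)
        cfg.transport.h_m = 0.0
        dT, dm = visf_rhs(270.0, cfg.m_w0, amb, cfg)
        assert dm == 0.0
        assert dT == pytest.approx(precondition_rhs(270.0, amb, cfg, cfg.m_w0), rel=1e-12)

    def test_evaporation_lowers_cooling_rate_derivative(self, cfg):
        amb = Ambient(T_b=270.0, T_g=260.0, T_c=265.0, T_u=265.0, p_t=1e3, p_w_c=0.0)
        dT_evap, dm = visf_rhs(270.0, cfg.m_w0, amb, cfg)
        assert dm < 0
        assert dT_evap < precondition_rhs(270.0, amb, cfg, cfg.m_w0)


class TestNucleationJump:
    def test_zero_supercooling(self, cfg):
        T_eq = equilibrium_freezing_point(cfg.m_w0, cfg.m_s, cfg.formulation)
        T_fl, m_i_n = nucleation_jump(T_eq, cfg.m_w0, cfg.m_s, cfg.thermo, cfg.formulation)
        assert m_i_n == 0.0
        assert T_fl == T_eq

    def test_default_supercooling_rises_to_272K(self, cfg):
        T_fl, m_i_n = nucleation_jump(263.18, cfg.m_w0, cfg.m_s, cfg.thermo, cfg.formulation)
        assert T_fl == pytest.approx(272.8, abs=0.1)
        assert 0 < m_i_n < cfg.m_w0

    def test_residuals_of_both_balances(self, cfg):
        f, th = cfg.formulation, cfg.thermo
        T_n, m_w = 263.18, cfg.m_w0
        T_fl, m_i_n = nucleation_jump(T_n, m_w, cfg.m_s, th, f)
        C = cfg.m_s * th.C_p_s + m_w * th.C_p_w
        r_energy = (T_fl - T_n) * C - m_i_n * th.dH_fus
        r_depress = (f.T_f_w - T_fl) - f.K_f * (cfg.m_s / f.M_s) / (m_w - m_i_n)
        assert abs(r_energy) / (m_i_n * th.dH_fus) < 1e-10
        assert abs(r_depress) / f.T_f_w < 1e-12

    def test_dense_scan_cross_check(self, cfg):
        """Brute-force 1-D scan over the ice mass finds the same root."""
        f, th = cfg.formulation, cfg.thermo
        T_n, m_w = 260.0, cfg.m_w0
        C = cfg.m_s * th.C_p_s + m_w * th.C_p_w
        grid = np.linspace(0.0, m_w * 0.99, 200001)
        res = (f.T_f_w - f.K_f * (cfg.m_s / f.M_s) / (m_w - grid)
               - (T_n + grid * th.dH_fus / C))
        brute = grid[np.argmin(np.abs(res))]
        _, m_i_n = nucleation_jump(T_n, m_w, cfg.m_s, th, f)
        assert m_i_n == pytest.approx(brute, abs=grid[1] - grid[0])

    def test_above_freezing_point_rejected(self, cfg):
        with pytest.raises(InfeasibleNucleationError):
            nucleation_jump(274.0, cfg.m_w0, cfg.m_s, cfg.thermo, cfg.formulation)


class TestNucleationProbability:
    def test_no_supercooling_no_rate(self, cfg):
        cfg.nucleation.k_n, cfg.nucleation.b_n = 1e-7, 10.0
        T_eq = equilibrium_freezing_point(cfg.m_w0, cfg.m_s, cfg.formulation)
        assert nucleation_probability_rhs(T_eq + 1.0, 0.0, cfg.m_w0, cfg) == 0.0

    def test_constant_rate_closed_form(self, cfg):
        """With b_n = 0 the intensity is constant and P follows the
        exponential survival law exactly."""
        cfg.nucleation.k_n, cfg.nucleation.b_n = 1e4, 0.0
        lam = 1e4 * cfg.formulation.V_l
        from scipy.integrate import solve_ivp
        sol = solve_ivp(lambda t, y: [nucleation_probability_rhs(265.0, y[0], cfg.m_w0, cfg)],
                        (0.0, 100.0), [0.0], rtol=1e-10, atol=1e-12, dense_output=True)
        t = np.linspace(0, 100, 20)
        assert sol.sol(t)[0] == pytest.approx(1 - np.exp(-lam * t), abs=1e-8)


class TestSolidificationGeometry:
    def test_start_of_solidification(self, cfg):
        g = solidification_geometry(cfg.m_w0, 0.0, cfg.m_s, cfg)
        assert g.r == pytest.approx(cfg.vial.r_o, rel=1e-12)
        assert g.l == 0.0
        assert g.h_l == pytest.approx(cfg.fill_height, rel=1e-12)

    def test_volume_closure(self, cfg):
        m_i = 1.5e-3
        m_w = cfg.m_w0 - m_i
        g = solidification_geometry(m_w, m_i, cfg.m_s, cfg)
        V_i = m_i / cfg.formulation.rho_i
        V_liq = m_w / cfg.formulation.rho_w + cfg.m_s / cfg.formulation.rho_s
        assert V_i + V_liq == pytest.approx(cfg.vial.A_z * g.H_tot, rel=1e-12)

    def test_full_solidification_height_matches_frozen_height(self, cfg):
        m_i = 0.999 * cfg.m_w0
        g = solidification_geometry(cfg.m_w0 - m_i, m_i, cfg.m_s, cfg)
        assert g.H_tot == pytest.approx(cfg.H, rel=0.01)


class TestSolidificationRhs:
    def test_adiabatic_stall(self, cfg):
        # ambient exactly at the slaved temperature: all loads vanish
        from lyosim.freezing import _solid_T_and_slope
        m_i = 1e-3
        T, _ = _solid_T_and_slope(m_i, cfg.m_w0, cfg)
        amb = Ambient(T_b=T, T_g=T, T_c=T, T_u=T, p_t=1e5, p_w_c=0.0)
        assert solidification_rhs(m_i, 0.0, amb, cfg, cfg.m_w0) == pytest.approx(0.0, abs=1e-18)

    def test_dilute_limit_is_classical_stefan_balance(self):
        """Nearly pure water: T pinned at the ice point and the freezing
        rate is the heat loss over the latent heat."""
        cfg = ModelConfig()
        cfg.formulation.x_s = 1e-9
        amb = Ambient(T_b=250.0, T_g=250.0, T_c=250.0, T_u=250.0, p_t=1e5, p_w_c=0.0)
        m_i = 1e-3
        got = solidification_rhs(m_i, 0.0, amb, cfg, cfg.m_w0)
        # independent recomputation of the heat loss at T ~ T_f,w
        from lyosim.config import SIGMA
        from lyosim.heat_transfer import (linearized_h_rad, overall_U_bottom,
                                          overall_U_side)
        T = cfg.formulation.T_f_w
        g = solidification_geometry(cfg.m_w0 - m_i, m_i, cfg.m_s, cfg)
        U2 = overall_U_bottom(10.0, g.l, 2.25)
        U3 = overall_U_side(8.0, g.r, g.r_o, 2.25)
        Ur = overall_U_side(linearized_h_rad(0.624, (250.0 + T) / 2), g.r, g.r_o, 2.25)
        A_z, A_r = cfg.vial.A_z, np.pi * cfg.vial.d * g.H_tot
        Q = (5.0 * A_z + U2 * A_z) * (250.0 - T) + A_r * (U3 + Ur) * (250.0 - T)
        assert got == pytest.approx(-Q / cfg.thermo.dH_fus, rel=1e-3)
        assert got > 0


class TestSimulateFreezing:
    def test_temperature_slaved_to_depression_curve(self, visf_case):
        res = simulate_freezing(visf_case.config, visf_case.protocols["freezing"],
                                mode="visf-deterministic", T0=280.0)
        sol = res.trajectory[res.trajectory.stage == "solidification"]
        f = visf_case.config.formulation
        a = visf_case.config.m_s / f.M_s
        T_slave = f.T_f_w - f.K_f * a / sol.m_w
        assert np.max(np.abs(sol["T"].to_numpy() - T_slave.to_numpy())) < 1e-9

    def test_mass_conservation(self, visf_case):
        res = simulate_freezing(visf_case.config, visf_case.protocols["freezing"],
                                mode="visf-deterministic", T0=280.0)
        traj = res.trajectory
        pre = traj[traj.stage == "precondition"]
        assert np.allclose(pre.m_w, visf_case.config.m_w0, rtol=1e-12)
        # after nucleation, water + ice inventory is constant
        after = traj[traj.stage.isin(["solidification", "cooling"])]
        total = (after.m_w + after.m_i).to_numpy()
        m_total = visf_case.config.m_w0 - res.evaporated_mass
        assert np.allclose(total, m_total, rtol=1e-9)

    def test_energy_audit_over_solidification(self, visf_case):
        """Integrated surface heat equals sensible plus latent change."""
        cfg = visf_case.config
        proto = visf_case.protocols["freezing"]
        res = simulate_freezing(cfg, proto, mode="visf-deterministic", T0=280.0)
        sol = res.trajectory[res.trajectory.stage == "solidification"]
        t = sol.t.to_numpy()
        m_i = sol.m_i.to_numpy()
        m_w_tot = (sol.m_w + sol.m_i).iloc[0]
        Q = np.array([solidification_rhs(m, tt, proto(tt), cfg, m_w_tot)
                      for m, tt in zip(m_i, t)])
        # dm_i/dt from the model equals the numerical slope of the output
        dmi_dt = np.gradient(m_i, t)
        assert np.corrcoef(Q, dmi_dt)[0, 1] > 0.999
        assert np.trapezoid(Q, t) == pytest.approx(m_i[-1] - m_i[0], rel=0.01)

    def test_deterministic_visf_run_is_reproducible(self, visf_case):
        r1 = simulate_freezing(visf_case.config, visf_case.protocols["freezing"],
                               mode="visf-deterministic", T0=280.0)
        r2 = simulate_freezing(visf_case.config, visf_case.protocols["freezing"],
                               mode="visf-deterministic", T0=280.0)
        assert r1.times == r2.times
        assert np.array_equal(r1.trajectory["T"], r2.trajectory["T"])

    def test_stochastic_run_reproducible_by_seed(self, visf_case):
        cfg = visf_case.config
        cfg.nucleation.k_n, cfg.nucleation.b_n = 1e-7, 10.0
        r1 = simulate_freezing(cfg, visf_case.protocols["freezing"],
                               mode="visf-stochastic", seed=7, T0=280.0,
                               stop_after="nucleation")
        r2 = simulate_freezing(cfg, visf_case.protocols["freezing"],
                               mode="visf-stochastic", seed=7, T0=280.0,
                               stop_after="nucleation")
        assert r1.u == r2.u
        assert r1.nucleation_time == r2.nucleation_time

    def test_lower_visf_pressure_nucleates_earlier(self):
        """The nucleation delay shrinks monotonically with VISF pressure;
        at 100 Pa the crash is near-immediate, at 10 kPa it takes minutes."""
        t_nuc = {}
        for p in (1e4, 1e3, 1e2):
            case = make_case("visf-study", visf_pressure=p)
            res = simulate_freezing(case.config, case.protocols["freezing"],
                                    mode="visf-deterministic", T0=280.0,
                                    stop_after="nucleation")
            t_nuc[p] = res.nucleation_time - res.times["t_f1"]
        assert t_nuc[1e2] < t_nuc[1e3] < t_nuc[1e4]
        assert t_nuc[1e2] < 120.0
        assert 180.0 < t_nuc[1e4] < 1500.0

    def test_solid_fraction_criterion_insensitivity(self, default_case):
        """Moving the end-of-solidification coefficient across 0.85-0.95
        changes the total freezing time by well under 10%."""
        times = []
        for frac in (0.85, 0.95):
            case = make_case("default")
            case.config.numerics.solid_fraction_end = frac
            res = simulate_freezing(case.config, case.protocols["freezing"],
                                    mode="visf-deterministic", T0=298.15)
            times.append(res.times["t_f5"])
        assert abs(times[1] - times[0]) / times[1] < 0.10

    def test_invalid_mode_rejected(self, default_case):
        with pytest.raises(InvalidParameterError):
            simulate_freezing(default_case.config,
                              default_case.protocols["freezing"], mode="bogus")

    def test_stochastic_requires_kinetics(self, default_case):
        with pytest.raises(InvalidParameterError):
            simulate_freezing(default_case.config,
                              default_case.protocols["freezing"],
                              mode="visf-stochastic", seed=1)
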