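"""Event-driven lumped model of the freezing step.

A suspended vial passes through up to five stages:

1. *preconditioning* — sensible cooling of the liquid by the cold gas and
   chamber surfaces;
2. *VISF* (vacuum-induced surface freezing) — the chamber pressure is
   lowered so that surface evaporation rapidly chills the liquid toward
   the nucleation temperature;
3. *nucleation* — an instantaneous, adiabatic jump: a supercooled liquid
   partially freezes and rises to its (depressed) equilibrium freezing
   point;
4. *solidification* — ice grows from the bottom and side surfaces while
   the remaining liquid tracks the freezing-point-depression curve;
5. *cooling* — sensible cooling of the mostly frozen product to the
   drying-stage start temperature.

Nucleation can be triggered deterministically at a prescribed temperature
``T_n`` or stochastically as the first event of an inhomogeneous Poisson
process with intensity ``lambda = k_n (T_f,l - T)^b_n V_l``.  The survival
probability is integrated alongside the energy balance
(``dP/dt = lambda (1 - P)``) and the trigger fires when ``P`` crosses a
uniform draw ``u``, which samples the first-event time exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .config import SIGMA, Ambient, InvalidParameterError, ModelConfig, Protocol
from .heat_transfer import linearized_h_rad, overall_U_bottom, overall_U_side

__all__ = [
    "psat_liquid", "dH_vap", "evaporation_flux", "equilibrium_freezing_point",
    "precondition_rhs", "visf_rhs", "nucleation_jump",
    "nucleation_probability_rhs", "solidification_geometry",
    "solidification_rhs", "simulate_freezing", "FreezingResult",
    "SolidificationGeometry", "InfeasibleNucleationError", "GeometryError",
]

T_CRIT = 647.1  # critical temperature of water [K]


class InfeasibleNucleationError(ValueError):
    """Nucleation jump has no physical root (liquid not supercooled)."""


class GeometryError(ValueError):
    """Solidification geometry closure failed (negative layer thickness)."""


# ---------------------------------------------------------------------------
# thermodynamic helpers
# ---------------------------------------------------------------------------

def psat_liquid(T):
    """Saturation pressure of liquid (supercooled) water [Pa].

    Antoine-type correlation ``p = 1e3 exp(16.3872 - 3885.7/(T - 42.98))``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 43.0) or np.any(T >= T_CRIT):
        raise InvalidParameterError("temperature outside the liquid-water correlation range")
    return 1e3 * np.exp(16.3872 - 3885.7 / (T - 42.98))


def dH_vap(T):
    """Latent heat of vaporization of water [J kg^-1].

    Watson-type scaling anchored at the normal boiling point, vanishing at
    the critical point: ``2.257e6 ((1 - T/647.1)/(1 - 373.15/647.1))^0.38``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or np.any(T > T_CRIT):
        raise InvalidParameterError("temperature outside the latent-heat correlation range")
    return 2.257e6 * ((1.0 - T / T_CRIT) / (1.0 - 373.15 / T_CRIT)) ** 0.38


def _vapor_mass_fraction(p_w: float, p_t: float, M_w: float, M_in: float) -> float:
    """Mass fraction of water in a water/inert binary vapor at partial
    pressure ``p_w`` and total pressure ``p_t`` (ideal gas)."""
    if p_w <= 0:
        return 0.0
    if p_w >= p_t:
        return 1.0
    return p_w * M_w / (p_w * M_w + (p_t - p_w) * M_in)


def evaporation_flux(T: float, p_t: float, p_w_c: float, h_m: float,
                     A_z: float, M_w: float, M_in: float) -> float:
    """Evaporative water-mass rate ``dm_w/dt`` [kg/s] at the liquid surface.

    ``dm_w/dt = -h_m A_z (x_w,sat - x_w,c)`` with the vapor-phase water
    mass fractions computed from the partial pressures.  When the
    saturation pressure exceeds the total pressure the interfacial vapor
    is pure water and the driving fraction saturates at 1, which caps the
    flux at its maximum value.
    """
    p_sat = float(psat_liquid(T))
    x_sat = _vapor_mass_fraction(p_sat, p_t, M_w, M_in)
    x_c = _vapor_mass_fraction(min(p_w_c, p_sat), p_t, M_w, M_in)
    return -h_m * A_z * max(x_sat - x_c, 0.0)


def equilibrium_freezing_point(m_w: float, m_s: float, formulation) -> float:
    """Depressed freezing point of the (ice-free) solution [K],
    ``T_f,l = T_f,w - K_f (m_s/M_s)/m_w``."""
    return formulation.T_f_w - formulation.K_f * (m_s / formulation.M_s) / m_w


# ---------------------------------------------------------------------------
# stage right-hand sides
# ---------------------------------------------------------------------------

def _liquid_side_area(m_w: float, m_s: float, cfg: ModelConfig) -> float:
    """Lateral area of the liquid column from volume additivity [m^2]."""
    V = m_w / cfg.formulation.rho_w + m_s / cfg.formulation.rho_s
    h = V / cfg.vial.A_z
    return cfg.vial.A_r(h)


def _liquid_heat_loads(T: float, amb: Ambient, cfg: ModelConfig, m_w: float) -> float:
    tp = cfg.transport
    A_z = cfg.vial.A_z
    A_r = _liquid_side_area(m_w, cfg.m_s, cfg)
    Q1 = tp.h_s1 * A_z * (amb.T_u - T)
    Q2 = tp.h_s2 * A_z * (amb.T_g - T)
    Q3 = tp.h_s3 * A_r * (amb.T_g - T) + SIGMA * A_r * tp.F_s3 * (amb.T_c ** 4 - T ** 4)
    return Q1 + Q2 + Q3


def precondition_rhs(T: float, amb: Ambient, cfg: ModelConfig, m_w: float) -> float:
    """``dT/dt`` during sensible-only cooling of the liquid."""
    C = cfg.m_s * cfg.thermo.C_p_s + m_w * cfg.thermo.C_p_w
    return _liquid_heat_loads(T, amb, cfg, m_w) / C


def visf_rhs(T: float, m_w: float, amb: Ambient, cfg: ModelConfig) -> tuple[float, float]:
    """``(dT/dt, dm_w/dt)`` during vacuum-induced surface freezing.

    The energy balance is the preconditioning balance plus the evaporative
    sink ``dH_vap * dm_w/dt`` (negative, since mass is lost).
    """
    if m_w <= 0:
        raise InvalidParameterError("liquid water exhausted during VISF")
    dm_w = evaporation_flux(T, amb.p_t, amb.p_w_c, cfg.transport.h_m,
                            cfg.vial.A_z, cfg.formulation.M_w, cfg.formulation.M_in)
    C = cfg.m_s * cfg.thermo.C_p_s + m_w * cfg.thermo.C_p_w
    dT = (_liquid_heat_loads(T, amb, cfg, m_w) + float(dH_vap(T)) * dm_w) / C
    return dT, dm_w


def nucleation_probability_rhs(T: float, P: float, m_w: float, cfg: ModelConfig) -> float:
    """``dP/dt = lambda (1 - P)`` for the cumulative first-nucleation
    probability; the intensity is clamped to zero without supercooling."""
    kin = cfg.nucleation
    T_fl = equilibrium_freezing_point(m_w, cfg.m_s, cfg.formulation)
    dT_super = max(T_fl - T, 0.0)
    lam = kin.k_n * dT_super ** kin.b_n * cfg.formulation.V_l
    return lam * (1.0 - P)


def nucleation_jump(T_n: float, m_w: float, m_s: float, thermo, formulation
                    ) -> tuple[float, float]:
    """Instantaneous adiabatic nucleation of a supercooled solution.

    Solves the coupled energy balance
    ``(T_f,l - T_n)(m_s C_p,s + m_w C_p,w) = m_i,n dH_fus``
    and molal freezing-point depression
    ``T_f,w - T_f,l = K_f (m_s/M_s)/(m_w - m_i,n)``
    for the post-nucleation temperature ``T_f,l`` and the ice mass
    ``m_i,n`` formed in the jump.
    """
    if m_w <= 0:
        raise InvalidParameterError("no liquid water to nucleate")
    C = m_s * thermo.C_p_s + m_w * thermo.C_p_w
    a = m_s / formulation.M_s

    T_eq = formulation.T_f_w - formulation.K_f * a / m_w
    if T_n >= T_eq:
        if T_n - T_eq < 1e-9:
            return T_n, 0.0
        raise InfeasibleNucleationError(
            f"nucleation temperature {T_n} K is above the equilibrium freezing point {T_eq:.3f} K")

    def residual(m_i):
        T_fl_dep = formulation.T_f_w - formulation.K_f * a / (m_w - m_i)
        T_fl_en = T_n + m_i * thermo.dH_fus / C
        return T_fl_dep - T_fl_en

    m_i_n = brentq(residual, 0.0, m_w * (1.0 - 1e-12), xtol=1e-18, rtol=1e-14)
    T_fl = T_n + m_i_n * thermo.dH_fus / C
    return T_fl, m_i_n


# ---------------------------------------------------------------------------
# solidification
# ---------------------------------------------------------------------------

@dataclass
class SolidificationGeometry:
    """Ice-shell geometry during solidification.

    The unfrozen liquid is modeled as a cylinder geometrically similar to
    the initial fill (radius ``r``, height ``h_l``); ice occupies a bottom
    slab of thickness ``l`` plus the annular shell around the liquid.
    """

    r: float       # liquid-cylinder radius [m]
    h_l: float     # liquid-cylinder height [m]
    l: float       # bottom ice-layer thickness [m]
    r_o: float     # vial inner radius [m]
    H_tot: float   # total product height [m]


def solidification_geometry(m_w: float, m_i: float, m_s: float,
                            cfg: ModelConfig) -> SolidificationGeometry:
    """Geometry closure for the shrinking liquid core.

    The liquid cylinder keeps the aspect ratio of the initial fill, so its
    radius and height both scale as ``(V_liq/V_l)^(1/3)``.  The bottom ice
    thickness follows from the ice-volume closure
    ``V_i = A_z l + (A_z - pi r^2) h_l``.
    """
    f = cfg.formulation
    A_z = cfg.vial.A_z
    r_o = cfg.vial.r_o
    V_liq = m_w / f.rho_w + m_s / f.rho_s
    V_liq0 = f.V_l
    s = (max(V_liq, 0.0) / V_liq0) ** (1.0 / 3.0)
    r = r_o * s
    h_l = cfg.fill_height * s
    V_i = m_i / f.rho_i
    l = (V_i - (A_z - np.pi * r ** 2) * h_l) / A_z
    if l < -1e-12 * cfg.fill_height:
        raise GeometryError("ice volume too small to wrap the liquid core (negative bottom layer)")
    l = max(l, 0.0)
    return SolidificationGeometry(r=r, h_l=h_l, l=l, r_o=r_o, H_tot=l + h_l)


def _solid_T_and_slope(m_i: float, m_w_total: float, cfg: ModelConfig) -> tuple[float, float]:
    """Temperature slaved to the depression curve and its slope dT/dm_i.

    ``m_w_total`` is the liquid water present when nucleation fired; the
    current liquid is ``m_w_total - m_i`` (mass conservation through the
    jump and solidification).
    """
    a = cfg.m_s / cfg.formulation.M_s
    m_w = m_w_total - m_i
    T = cfg.formulation.T_f_w - cfg.formulation.K_f * a / m_w
    dT_dmi = -cfg.formulation.K_f * a / m_w ** 2
    return T, dT_dmi


def solidification_rhs(m_i: float, t: float, amb: Ambient, cfg: ModelConfig,
                       m_w_total: float) -> float:
    """``dm_i/dt`` during solidification.

    The product temperature is slaved algebraically to the depression
    curve ``T(m_i)``, which turns the energy balance into a single ODE:
    ``dm_i/dt = (Q_s1 + Q_s2 + Q_s3) / (C_eff dT/dm_i - dH_fus)``.
    The growing ice is an extra series resistance: the bottom load passes
    through the slab, and the side convection and (linearized) side
    radiation both pass through the cylindrical shell.
    """
    th, tp = cfg.thermo, cfg.transport
    T, dT_dmi = _solid_T_and_slope(m_i, m_w_total, cfg)
    m_w = m_w_total - m_i
    geo = solidification_geometry(m_w, m_i, cfg.m_s, cfg)

    A_z = cfg.vial.A_z
    A_r = cfg.vial.A_r(geo.H_tot)
    U_s2 = overall_U_bottom(tp.h_s2, geo.l, th.k_i)
    r_eff = max(geo.r, 1e-6 * geo.r_o)    # shell resistance diverges as the core vanishes
    U_s3 = overall_U_side(tp.h_s3, r_eff, geo.r_o, th.k_i)
    h_rad = linearized_h_rad(tp.F_s3, 0.5 * (amb.T_c + T))
    U_rad = overall_U_side(h_rad, r_eff, geo.r_o, th.k_i)

    Q1 = tp.h_s1 * A_z * (amb.T_u - T)
    Q2 = U_s2 * A_z * (amb.T_g - T)
    Q3 = A_r * (U_s3 * (amb.T_g - T) + U_rad * (amb.T_c - T))

    C_eff = cfg.m_s * th.C_p_s + m_w * th.C_p_w
    denom = C_eff * dT_dmi - th.dH_fus   # strictly negative
    return (Q1 + Q2 + Q3) / denom


def _cooling_rhs(T: float, amb: Ambient, cfg: ModelConfig, m_w: float,
                 m_i: float, A_r: float) -> float:
    """Sensible cooling of the frozen product (constant masses/geometry)."""
    th, tp = cfg.thermo, cfg.transport
    A_z = cfg.vial.A_z
    Q1 = tp.h_s1 * A_z * (amb.T_u - T)
    Q2 = tp.h_s2 * A_z * (amb.T_g - T)
    Q3 = tp.h_s3 * A_r * (amb.T_g - T) + SIGMA * A_r * tp.F_s3 * (amb.T_c ** 4 - T ** 4)
    C = cfg.m_s * th.C_p_s + m_w * th.C_p_w + m_i * th.C_p_i
    return (Q1 + Q2 + Q3) / C


# ---------------------------------------------------------------------------
# full freezing simulation
# ---------------------------------------------------------------------------

@dataclass
class FreezingResult:
    """Trajectory and stage bookkeeping for one freezing run."""

    trajectory: pd.DataFrame
    times: dict = field(default_factory=dict)       # t_f1 ... t_f5 [s]
    T_nucleation: Optional[float] = None            # product T when nucleation fired [K]
    T_fl: Optional[float] = None                    # post-jump temperature [K]
    m_i_n: Optional[float] = None                   # ice formed in the jump [kg]
    evaporated_mass: float = 0.0                    # water lost during VISF [kg]
    final_state: dict = field(default_factory=dict)
    completed: bool = True
    mode: str = "visf-deterministic"
    u: Optional[float] = None

    @property
    def nucleation_time(self) -> Optional[float]:
        return self.times.get("t_f3")


_MODES = ("uncontrolled-deterministic", "uncontrolled-stochastic",
          "visf-deterministic", "visf-stochastic")


def simulate_freezing(cfg: ModelConfig, protocol: Protocol,
                      mode: str = "visf-deterministic",
                      seed: Optional[int] = None, u: Optional[float] = None,
                      t0: float = 0.0, T0: float = 298.15,
                      stop_after: str = "cooling",
                      n_out_per_stage: int = 300) -> FreezingResult:
    """Simulate the freezing step through all configured stages.

    Parameters
    ----------
    cfg, protocol :
        Model parameters and the ambient schedule.  ``protocol.visf_start``
        must be set for the VISF modes.
    mode : str
        One of ``uncontrolled-deterministic``, ``uncontrolled-stochastic``,
        ``visf-deterministic``, ``visf-stochastic``.  Deterministic modes
        nucleate when ``T`` falls to ``cfg.nucleation.T_n``; stochastic
        modes nucleate when the cumulative probability crosses a uniform
        draw ``u`` (sampled from ``seed`` unless given explicitly).
    stop_after : str
        ``"nucleation"`` stops right after the jump (useful for nucleation
        statistics); ``"cooling"`` runs the full stage sequence.
    """
    if mode not in _MODES:
        raise InvalidParameterError(f"mode must be one of {_MODES}, got {mode!r}")
    stochastic = mode.endswith("stochastic")
    with_visf = mode.startswith("visf")
    if stochastic:
        cfg.nucleation.require_stochastic()
        if u is None:
            u = float(np.random.default_rng(seed).random())
        if not (0.0 < u < 1.0):
            raise InvalidParameterError("u must lie in (0, 1)")
    if with_visf and protocol.visf_start is None:
        raise InvalidParameterError("protocol.visf_start must be set for VISF modes")

    num = cfg.numerics
    m_w0 = cfg.m_w0
    frames = []
    times: dict = {}

    def liquid_rhs(t, y, evaporating):
        T, m_w, P = y
        amb = protocol(t)
        if evaporating:
            dT, dm_w = visf_rhs(T, m_w, amb, cfg)
        else:
            dT, dm_w = precondition_rhs(T, amb, cfg, m_w), 0.0
        dP = nucleation_probability_rhs(T, P, m_w, cfg) if stochastic else 0.0
        return [dT, dm_w, dP]

    def temp_event(t, y, evaporating):
        return y[0] - cfg.nucleation.T_n
    temp_event.terminal = True
    temp_event.direction = -1.0

    def prob_event(t, y, evaporating):
        return y[2] - u
    prob_event.terminal = True
    prob_event.direction = 1.0

    nuc_event = prob_event if stochastic else temp_event

    def integrate_liquid(t_start, t_end, y0, evaporating, stage):
        sol = solve_ivp(liquid_rhs, (t_start, t_end), y0, method="LSODA",
                        rtol=num.rtol, atol=[1e-8, 1e-15, 1e-10],
                        dense_output=True, events=[nuc_event],
                        args=(evaporating,))
        if not sol.success:
            raise RuntimeError(f"freezing integrator failed in stage {stage!r}: {sol.message}")
        t_stop = sol.t_events[0][0] if sol.t_events[0].size else sol.t[-1]
        ts = np.linspace(t_start, t_stop, n_out_per_stage)
        ys = sol.sol(ts)
        frames.append(pd.DataFrame({"t": ts, "stage": stage, "T": ys[0],
                                    "m_w": ys[1], "m_i": 0.0, "P": ys[2]}))
        fired = sol.t_events[0].size > 0
        return t_stop, sol.sol(t_stop), fired

    # --- stage 1: preconditioning -----------------------------------------
    y = [T0, m_w0, 0.0]
    t = t0
    fired = False
    if with_visf:
        t_visf = t0 + protocol.visf_start
        t, y, fired = integrate_liquid(t, t_visf, y, False, "precondition")
        times["t_f1"] = t
        if not fired:
            # --- stage 2: VISF -------------------------------------------
            t, y, fired = integrate_liquid(t, t0 + num.max_time, y, True, "visf")
            times["t_f2"] = t
    else:
        t, y, fired = integrate_liquid(t, t0 + num.max_time, y, False, "precondition")
        times["t_f1"] = times["t_f2"] = t

    T_nuc, m_w_nuc, P_nuc = float(y[0]), float(y[1]), float(y[2])
    evaporated = m_w0 - m_w_nuc
    if not fired:
        warnings.warn("nucleation was not reached within the integration horizon; "
                      "returning the partial trajectory", RuntimeWarning)
        return FreezingResult(trajectory=pd.concat(frames, ignore_index=True),
                              times=times, evaporated_mass=evaporated,
                              completed=False, mode=mode, u=u,
                              final_state={"T": T_nuc, "m_w": m_w_nuc, "m_i": 0.0})

    # --- stage 3: nucleation jump (instantaneous) -------------------------
    T_fl, m_i_n = nucleation_jump(T_nuc, m_w_nuc, cfg.m_s, cfg.thermo, cfg.formulation)
    times["t_f3"] = t
    m_w3 = m_w_nuc - m_i_n
    frames.append(pd.DataFrame({"t": [t, t], "stage": "nucleation",
                                "T": [T_nuc, T_fl], "m_w": [m_w_nuc, m_w3],
                                "m_i": [0.0, m_i_n], "P": P_nuc}))
    result = FreezingResult(trajectory=None, times=times, T_nucleation=T_nuc,
                            T_fl=T_fl, m_i_n=m_i_n, evaporated_mass=evaporated,
                            mode=mode, u=u)
    if stop_after == "nucleation":
        result.trajectory = pd.concat(frames, ignore_index=True)
        result.final_state = {"T": T_fl, "m_w": m_w3, "m_i": m_i_n}
        return result

    # --- stage 4: solidification ------------------------------------------
    # end criterion: m_i(t_f4) = f * m_w(t_f3), the post-jump liquid water
    m_i_end = num.solid_fraction_end * m_w3
    m_w_total = m_w_nuc    # conserved water+ice inventory through the stage

    def solid_rhs(tt, yy):
        return [solidification_rhs(yy[0], tt, protocol(tt), cfg, m_w_total)]

    def solid_event(tt, yy):
        return yy[0] - m_i_end
    solid_event.terminal = True
    solid_event.direction = 1.0

    if m_i_end <= m_i_n:
        # deep supercooling already froze past the end criterion in the jump
        t_end, m_i4 = t, m_i_n
    else:
        sol = solve_ivp(solid_rhs, (t, t + num.max_time), [m_i_n], method="LSODA",
                        rtol=num.rtol, atol=1e-12, dense_output=True,
                        events=[solid_event])
        if not sol.success:
            raise RuntimeError(f"solidification integrator failed: {sol.message}")
        if not sol.t_events[0].size:
            warnings.warn("solidification did not complete within the horizon",
                          RuntimeWarning)
            result.completed = False
        t_end = sol.t_events[0][0] if sol.t_events[0].size else sol.t[-1]
        ts = np.linspace(t, t_end, n_out_per_stage)
        mi = sol.sol(ts)[0]
        Tsol = np.array([_solid_T_and_slope(m, m_w_total, cfg)[0] for m in mi])
        frames.append(pd.DataFrame({"t": ts, "stage": "solidification", "T": Tsol,
                                    "m_w": m_w_total - mi, "m_i": mi, "P": P_nuc}))
        m_i4 = float(sol.sol(t_end)[0])
    times["t_f4"] = t_end
    t = t_end
    m_w4 = m_w_total - m_i4
    T4 = _solid_T_and_slope(m_i4, m_w_total, cfg)[0]

    # --- stage 5: final cooling -------------------------------------------
    A_r = cfg.vial.A_r(solidification_geometry(m_w4, m_i4, cfg.m_s, cfg).H_tot)

    def cool_rhs(tt, yy):
        return [_cooling_rhs(yy[0], protocol(tt), cfg, m_w4, m_i4, A_r)]

    def cool_event(tt, yy):
        return yy[0] - num.cooling_target
    cool_event.terminal = True
    cool_event.direction = -1.0

    sol = solve_ivp(cool_rhs, (t, t + num.max_time), [T4], method="LSODA",
                    rtol=num.rtol, atol=1e-8, dense_output=True,
                    events=[cool_event])
    if not sol.success:
        raise RuntimeError(f"cooling integrator failed: {sol.message}")
    if not sol.t_events[0].size:
        warnings.warn("cooling target was not reached within the horizon; "
                      "using the final temperature", RuntimeWarning)
        result.completed = False
    t_end = sol.t_events[0][0] if sol.t_events[0].size else sol.t[-1]
    ts = np.linspace(t, t_end, n_out_per_stage)
    Tc = sol.sol(ts)[0]
    frames.append(pd.DataFrame({"t": ts, "stage": "cooling", "T": Tc,
                                "m_w": m_w4, "m_i": m_i4, "P": P_nuc}))
    times["t_f5"] = t_end

    result.trajectory = pd.concat(frames, ignore_index=True)
    result.final_state = {"T": float(sol.sol(t_end)[0]), "m_w": m_w4, "m_i": m_i4}
    return result
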