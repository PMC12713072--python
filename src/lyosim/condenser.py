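"""Chamber water-vapor balance for condenser-failure / choked-flow studies.

During normal operation the condenser removes vapor at least as fast as
the vials produce it and the chamber water partial pressure stays at its
setpoint.  If the total sublimation flow ``j_w = n_vial A_z N_w`` exceeds
the condenser capacity ``j_w,max``, vapor accumulates and the chamber
pressure rises:

``dp_w,c/dt = (j_w - j_w,max) R T_bar / (V_c M_w)``

A rising chamber pressure feeds back on the sublimation driving force, so
the pressure climbs until the per-vial flux has throttled itself down to
the condenser capacity and then plateaus.  Here the balance is coupled
two-way with the primary-drying model: ``p_w,c`` becomes a dynamic state
replacing the protocol channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import R_GAS, InvalidParameterError, ModelConfig, Protocol
from .primary import PrimaryResult, interface_velocity, primary_rhs, sublimation_flux

__all__ = ["CondenserParams", "chamber_vapor_rhs", "simulate_primary_with_condenser"]


@dataclass
class CondenserParams:
    """Condenser and chamber parameters for the failure scenario."""

    j_w_max: float = 1.8e-5    # maximum condenser capacity [kg s^-1]
    V_c: float = 0.118         # chamber volume [m^3]
    T_bar: float = 260.0       # mean chamber gas temperature [K], held constant
    n_vial: int = 200          # number of vials in the chamber

    def __post_init__(self):
        if min(self.j_w_max, self.V_c, self.T_bar) <= 0 or self.n_vial <= 0:
            raise InvalidParameterError("condenser parameters must be positive")


def chamber_vapor_rhs(p_w_c: float, N_w: float, params: CondenserParams,
                      A_z: float, M_w: float = 0.018,
                      p_floor: float = 0.0) -> float:
    """``dp_w,c/dt`` for the chamber vapor balance [Pa/s].

    Excess condenser capacity is only used to work off accumulated vapor:
    once the chamber is back at the operating setpoint ``p_floor`` the
    pressure is held there (an oversized condenser therefore reproduces
    constant-pressure operation exactly, and the pressure can never go
    negative).
    """
    j_w = params.n_vial * A_z * N_w
    rate = (j_w - params.j_w_max) * R_GAS * params.T_bar / (params.V_c * M_w)
    if p_w_c <= p_floor and rate < 0.0:
        return 0.0
    return rate


def simulate_primary_with_condenser(cfg: ModelConfig, protocol: Protocol,
                                    condenser: CondenserParams, T0=235.0,
                                    p_w_c0: float = 3.0, t0: float = 0.0,
                                    n_out: int = 400,
                                    t_max: float | None = None) -> PrimaryResult:
    """Primary drying with the chamber water pressure as a dynamic state.

    Identical to :func:`lyosim.primary.simulate_primary` except that the
    state vector is augmented with ``p_w_c`` and the sublimation driving
    force uses the evolving chamber pressure.  The returned summary gains
    a ``p_w_c`` column.
    """
    num = cfg.numerics
    n = num.n_z
    H = cfg.H
    M_w = cfg.formulation.M_w
    A_z = cfg.vial.A_z
    if t_max is None:
        t_max = num.max_time

    y0 = np.empty(n + 2)
    y0[:n] = np.broadcast_to(np.asarray(T0, dtype=float), (n,))
    y0[n] = num.front_floor * H
    y0[n + 1] = p_w_c0
    S_end = (1.0 - num.front_end_fraction) * H

    def rhs(t, y):
        p = max(y[n + 1], 0.0)
        core = primary_rhs(t, y[:n + 1], cfg, protocol, p_w_c_override=p)
        N_w = float(sublimation_flux(y[0], y[n], p, cfg.transport))
        dp = chamber_vapor_rhs(p, N_w, condenser, A_z, M_w, p_floor=p_w_c0)
        return np.concatenate([core, [dp]])

    def event_front(t, y):
        return y[n] - S_end
    event_front.terminal = True
    event_front.direction = 1.0

    atol = np.full(n + 2, 1e-6)
    atol[n] = 1e-12
    atol[n + 1] = 1e-8
    sol = solve_ivp(rhs, (t0, t0 + t_max), y0, method="BDF", rtol=num.rtol,
                    atol=atol, dense_output=True, events=[event_front])
    if not sol.success:
        raise RuntimeError(f"coupled condenser integrator failed: {sol.message}")

    completed = sol.t_events[0].size > 0
    t_end = sol.t_events[0][0] if completed else sol.t[-1]
    if not completed:
        warnings.warn("primary drying (condenser-coupled) did not finish "
                      "within the horizon", RuntimeWarning)

    ts = np.linspace(t0, t_end, n_out)
    ys = sol.sol(ts)
    T = ys[:n]
    S = ys[n]
    p = np.maximum(ys[n + 1], 0.0)
    N_w = np.array([float(sublimation_flux(T[0, k], S[k], p[k], cfg.transport))
                    for k in range(ts.size)])
    summary = pd.DataFrame({"t": ts, "S": S, "N_w": N_w, "T_front": T[0],
                            "T_bottom": T[-1], "T_max": T.max(axis=0),
                            "T_min": T.min(axis=0), "p_w_c": p})

    dxi = 1.0 / (n - 1)
    xi = np.arange(n) * dxi
    zz = S[None, :] + xi[:, None] * (H - S[None, :])
    profiles = pd.DataFrame({"t": np.repeat(ts, n), "z": zz.T.ravel(),
                             "T": T.T.ravel()})

    yf = sol.sol(t_end)
    t_d1 = t_end
    if completed:
        dSdt = float(interface_velocity(
            sublimation_flux(yf[0], yf[n], max(yf[n + 1], 0.0), cfg.transport),
            cfg.rho_f, cfg.thermo.rho_e))
        if dSdt > 0:
            t_d1 = t_end + (H - yf[n]) / dSdt

    return PrimaryResult(summary=summary, profiles=profiles, t_d1=t_d1,
                         final_T=yf[:n], completed=completed,
                         extras={"p_w_c_final": float(max(yf[n + 1], 0.0))})
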