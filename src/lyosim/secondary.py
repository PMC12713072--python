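"""Secondary drying: conduction in the dried cake with bound-water desorption.

The dried cake occupies ``0 <= z <= H``.  Heat conducts vertically with
effective properties (solid + gas in the pores), the bottom is heated
through a film coefficient, the top exchanges radiation with the upper
chamber surface, and the side wall radiates as a volumetric source.
Bound water desorbs following first-order linear-driving-force kinetics
with an Arrhenius rate constant, which enters the energy balance as a
distributed heat sink.  The run terminates when the spatial mean of the
bound-water concentration falls to the residual-moisture target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import R_GAS, SIGMA, ModelConfig, Protocol

__all__ = ["desorption_rate_constant", "desorption_rate", "secondary_rhs",
           "simulate_secondary", "SecondaryResult"]


def desorption_rate_constant(T, desorption):
    """Arrhenius desorption rate constant ``k_d = f_a exp(-E_a/RT)`` [s^-1]."""
    T = np.asarray(T, dtype=float)
    return desorption.f_a * np.exp(-desorption.E_a / (R_GAS * T))


def desorption_rate(T, c_w, desorption):
    """Linear-driving-force desorption ``dc_w/dt = k_d (c_w_eq - c_w)``
    [kg/kg/s] (negative while ``c_w > c_w_eq``)."""
    return desorption_rate_constant(T, desorption) * (desorption.c_w_eq - np.asarray(c_w, float))


def secondary_rhs(t: float, y: np.ndarray, cfg: ModelConfig,
                  protocol: Protocol) -> np.ndarray:
    """Method-of-lines right-hand side, ``y = [T_1..T_nz, c_1..c_nz]``
    with node 1 at the cake top (``z = 0``) and node ``n_z`` at the bottom."""
    th, tp = cfg.thermo, cfg.transport
    n = cfg.numerics.n_z
    T = y[:n]
    c = y[n:]
    amb = protocol(t)
    dz = cfg.H / (n - 1)

    dc = desorption_rate(T, c, cfg.desorption)

    # ghost values: radiative top, Newton bottom
    q_top = SIGMA * tp.F_s1 * (amb.T_u ** 4 - T[0] ** 4)
    T_ghost_top = T[1] + 2.0 * dz / th.k_e * q_top
    T_ghost_bot = T[n - 2] - 2.0 * dz * tp.h_b / th.k_e * (T[n - 1] - amb.T_b)

    Te = np.empty(n + 2)
    Te[0] = T_ghost_top
    Te[1:-1] = T
    Te[-1] = T_ghost_bot

    kappa = th.k_e / (th.rho_e * th.C_p_e)
    q_side = 4.0 * SIGMA * tp.F_s3 * (amb.T_c ** 4 - T ** 4) / cfg.vial.d

    dT = (kappa * (Te[2:] - 2.0 * Te[1:-1] + Te[:-2]) / dz ** 2
          + th.rho_d * th.dH_des / (th.rho_e * th.C_p_e) * dc
          + q_side / (th.rho_e * th.C_p_e))
    return np.concatenate([dT, dc])


@dataclass
class SecondaryResult:
    """Spatiotemporal output of a secondary-drying run."""

    summary: pd.DataFrame        # t, c_w_mean, T_bottom, T_top, T_max
    profiles: pd.DataFrame       # long format: t, z, T, c_w
    t_d2: float
    final_T: np.ndarray
    final_c_w: np.ndarray
    completed: bool = True


def simulate_secondary(cfg: ModelConfig, protocol: Protocol, T0=273.0,
                       c_w0=None, t0: float = 0.0, n_out: int = 300,
                       t_max: Optional[float] = None) -> SecondaryResult:
    """Integrate secondary drying until the mean residual moisture reaches
    the target ``c_w_inf``.

    ``T0`` and ``c_w0`` may be scalars (uniform) or arrays with one value
    per grid node; ``c_w0`` defaults to the configured uniform initial
    concentration.
    """
    num = cfg.numerics
    n = num.n_z
    des = cfg.desorption
    if c_w0 is None:
        c_w0 = des.c_w_0
    if t_max is None:
        t_max = num.max_time

    y0 = np.concatenate([
        np.broadcast_to(np.asarray(T0, dtype=float), (n,)),
        np.broadcast_to(np.asarray(c_w0, dtype=float), (n,)),
    ])

    w = _trapezoid_weights(n)

    def event_dry(t, y, *args):
        return float(w @ y[n:]) - des.c_w_inf
    event_dry.terminal = True
    event_dry.direction = -1.0

    if float(w @ y0[n:]) <= des.c_w_inf:
        # degenerate: already at or below target
        profiles = pd.DataFrame({"t": t0, "z": np.linspace(0, cfg.H, n),
                                 "T": y0[:n], "c_w": y0[n:]})
        summary = pd.DataFrame({"t": [t0], "c_w_mean": [float(w @ y0[n:])],
                                "T_bottom": [y0[n - 1]], "T_top": [y0[0]],
                                "T_max": [y0[:n].max()]})
        return SecondaryResult(summary=summary, profiles=profiles, t_d2=t0,
                               final_T=y0[:n].copy(), final_c_w=y0[n:].copy())

    atol = np.concatenate([np.full(n, 1e-6), np.full(n, 1e-10)])
    sol = solve_ivp(secondary_rhs, (t0, t0 + t_max), y0, method="BDF",
                    rtol=num.rtol, atol=atol, dense_output=True,
                    events=[event_dry], args=(cfg, protocol))
    if not sol.success:
        raise RuntimeError(f"secondary-drying integrator failed: {sol.message}")

    completed = sol.t_events[0].size > 0
    t_end = sol.t_events[0][0] if completed else sol.t[-1]
    if not completed:
        warnings.warn("secondary drying did not reach the moisture target "
                      "within the horizon", RuntimeWarning)

    ts = np.linspace(t0, t_end, n_out)
    ys = sol.sol(ts)
    T = ys[:n]
    c = ys[n:]
    z = np.linspace(0.0, cfg.H, n)

    summary = pd.DataFrame({"t": ts, "c_w_mean": w @ c, "T_bottom": T[-1],
                            "T_top": T[0], "T_max": T.max(axis=0)})
    profiles = pd.DataFrame({"t": np.repeat(ts, n), "z": np.tile(z, ts.size),
                             "T": T.T.ravel(), "c_w": c.T.ravel()})

    yf = sol.sol(t_end)
    return SecondaryResult(summary=summary, profiles=profiles, t_d2=t_end,
                           final_T=yf[:n], final_c_w=yf[n:],
                           completed=completed)


def _trapezoid_weights(n: int) -> np.ndarray:
    """Normalized trapezoid weights for the volume-average over z."""
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return w / (n - 1)
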