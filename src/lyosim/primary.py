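"""Primary drying: 1-D sublimation with a moving front (Stefan problem).

The frozen region ``S(t) < z < H`` conducts heat in the vertical
direction, receives side-wall radiation as a volumetric source, is heated
from below through a film coefficient, and loses the latent heat of
sublimation at the receding front ``z = S(t)``.  The sublimation flux is
driven by the ice saturation pressure at the front against the chamber
water partial pressure through an empirical, thickness-dependent dried
cake resistance.

The moving domain is mapped onto the fixed interval ``xi = (z - S)/(H - S)
in [0, 1]`` (a Landau transformation), discretized with second-order
central differences (method of lines) and integrated with a stiff solver.
Both boundary conditions are imposed by ghost-point elimination, and the
run terminates on the event ``S = H`` (to within a small numerical
fraction of ``H``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import SIGMA, ModelConfig, Protocol

__all__ = ["psat_ice", "cake_resistance", "sublimation_flux",
           "interface_velocity", "primary_rhs", "simulate_primary",
           "PrimaryResult"]


def psat_ice(T):
    """Saturation (sublimation) pressure over ice [Pa]:
    ``p = exp(-6139.9/T + 28.8912)``."""
    T = np.asarray(T, dtype=float)
    return np.exp(-6139.9 / T + 28.8912)


def cake_resistance(S, transport):
    """Dried-cake mass-transfer resistance ``R_p = R_p0 + R_p1 S/(R_p2 + S)``.

    Monotone nondecreasing in the dried-layer thickness ``S`` and bounded
    by ``R_p0 + R_p1``.
    """
    S = np.asarray(S, dtype=float)
    return transport.R_p0 + transport.R_p1 * S / (transport.R_p2 + S)


def sublimation_flux(T_front, S, p_w_c, transport):
    """Sublimation mass flux ``N_w = (p_sat(T_front) - p_w,c)/R_p``
    [kg m^-2 s^-1], floored at zero (no resublimation from the chamber)."""
    N = (psat_ice(T_front) - p_w_c) / cake_resistance(S, transport)
    return np.maximum(N, 0.0)


def interface_velocity(N_w, rho_f, rho_e):
    """Front recession rate ``dS/dt = N_w/(rho_f - rho_e)`` [m/s]."""
    if rho_f <= rho_e:
        raise ValueError("frozen density must exceed the dried effective density")
    return N_w / (rho_f - rho_e)


def primary_rhs(t: float, y: np.ndarray, cfg: ModelConfig, protocol: Protocol,
                p_w_c_override: Optional[float] = None) -> np.ndarray:
    """Method-of-lines right-hand side on the transformed grid.

    ``y = [T_1 ... T_nz, S]`` with node 1 at the front (``xi = 0``) and
    node ``n_z`` at the vial bottom (``xi = 1``).  Returns
    ``[dT_1/dt ... dT_nz/dt, dS/dt]``.
    """
    th, tp = cfg.thermo, cfg.transport
    n = cfg.numerics.n_z
    T = y[:n]
    S = y[n]
    H = cfg.H
    amb = protocol(t)
    p_w_c = amb.p_w_c if p_w_c_override is None else p_w_c_override

    L = H - S                      # frozen-layer thickness (metric of the map)
    dxi = 1.0 / (n - 1)
    xi = np.arange(n) * dxi
    alpha = th.k_f / (cfg.rho_f * th.C_p_f)

    N_w = float(sublimation_flux(T[0], S, p_w_c, tp))
    dSdt = float(interface_velocity(N_w, cfg.rho_f, th.rho_e))

    # ghost values from the boundary conditions
    # front (j=1): N_w dH_sub = k_f/L * dT/dxi + sigma F_s1 (T_u^4 - T^4)
    q_top = SIGMA * tp.F_s1 * (amb.T_u ** 4 - T[0] ** 4)
    T_ghost_front = T[1] - 2.0 * dxi * L / th.k_f * (N_w * th.dH_sub - q_top)
    # bottom (j=n_z): -k_f/L * dT/dxi = h_b (T - T_b)
    T_ghost_bot = T[n - 2] - 2.0 * dxi * L * tp.h_b / th.k_f * (T[n - 1] - amb.T_b)

    Te = np.empty(n + 2)
    Te[0] = T_ghost_front
    Te[1:-1] = T
    Te[-1] = T_ghost_bot

    d2T = (Te[2:] - 2.0 * Te[1:-1] + Te[:-2]) / dxi ** 2
    dT1 = (Te[2:] - Te[:-2]) / (2.0 * dxi)
    # side-wall radiation per unit frozen volume: A_r/V_f = 4/d locally
    q_side = 4.0 * SIGMA * tp.F_s3 * (amb.T_c ** 4 - T ** 4) / cfg.vial.d

    dTdt = (alpha / L ** 2 * d2T
            - (xi - 1.0) / L * dSdt * dT1
            + q_side / (cfg.rho_f * th.C_p_f))

    out = np.empty(n + 1)
    out[:n] = dTdt
    out[n] = dSdt
    return out


@dataclass
class PrimaryResult:
    """Spatiotemporal output of a primary-drying run."""

    summary: pd.DataFrame        # t, S, N_w, T_front, T_bottom, T_max [+ p_w_c]
    profiles: pd.DataFrame       # long format: t, z, T
    t_d1: float                  # end of primary drying [s]
    final_T: np.ndarray          # temperature profile at t_d1 (front -> bottom)
    completed: bool = True
    extras: dict = field(default_factory=dict)


def simulate_primary(cfg: ModelConfig, protocol: Protocol, T0=235.0,
                     t0: float = 0.0, n_out: int = 300,
                     t_max: Optional[float] = None) -> PrimaryResult:
    """Integrate primary drying until the front reaches the product bottom.

    Parameters
    ----------
    T0 : float or array
        Initial temperature, uniform scalar or one value per grid node.
    t_max : float, optional
        Horizon cap; if the front has not consumed the frozen layer by
        then, a truncated result is returned with ``completed=False``.

    Notes
    -----
    The front starts at a small numerical floor ``S(t0) = eps H`` to keep
    the transformed metric finite, and the terminal event fires at
    ``S = (1 - front_end_fraction) H``; the reported ``t_d1`` linearly
    extrapolates the last front velocity to ``S = H``.
    """
    num = cfg.numerics
    n = num.n_z
    H = cfg.H
    if t_max is None:
        t_max = num.max_time

    y0 = np.empty(n + 1)
    y0[:n] = np.broadcast_to(np.asarray(T0, dtype=float), (n,))
    y0[n] = num.front_floor * H
    S_end = (1.0 - num.front_end_fraction) * H

    def event_front(t, y, *args):
        return y[n] - S_end
    event_front.terminal = True
    event_front.direction = 1.0

    atol = np.full(n + 1, 1e-6)
    atol[n] = 1e-12
    sol = solve_ivp(primary_rhs, (t0, t0 + t_max), y0, method="BDF",
                    rtol=num.rtol, atol=atol, dense_output=True,
                    events=[event_front], args=(cfg, protocol))
    if not sol.success:
        raise RuntimeError(f"primary-drying integrator failed: {sol.message}")

    completed = sol.t_events[0].size > 0
    t_end = sol.t_events[0][0] if completed else sol.t[-1]
    if not completed:
        warnings.warn("primary drying did not finish within the horizon",
                      RuntimeWarning)

    ts = np.linspace(t0, t_end, n_out)
    ys = sol.sol(ts)
    T = ys[:n]
    S = ys[n]
    ambs = [protocol(t) for t in ts]
    p_w_c = np.array([a.p_w_c for a in ambs])
    N_w = np.array([float(sublimation_flux(T[0, k], S[k], p_w_c[k], cfg.transport))
                    for k in range(ts.size)])

    summary = pd.DataFrame({"t": ts, "S": S, "N_w": N_w, "T_front": T[0],
                            "T_bottom": T[-1], "T_max": T.max(axis=0),
                            "T_min": T.min(axis=0)})

    dxi = 1.0 / (n - 1)
    xi = np.arange(n) * dxi
    zz = S[None, :] + xi[:, None] * (H - S[None, :])
    profiles = pd.DataFrame({
        "t": np.repeat(ts, n),
        "z": zz.T.ravel(),
        "T": T.T.ravel(),
    })

    yf = sol.sol(t_end)
    t_d1 = t_end
    if completed:
        dSdt_end = float(interface_velocity(
            sublimation_flux(yf[0], yf[n], protocol(t_end).p_w_c, cfg.transport),
            cfg.rho_f, cfg.thermo.rho_e))
        if dSdt_end > 0:
            t_d1 = t_end + (H - yf[n]) / dSdt_end

    return PrimaryResult(summary=summary, profiles=profiles, t_d1=t_d1,
                         final_T=yf[:n], completed=completed)
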