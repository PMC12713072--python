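"""Full-cycle orchestration and Monte-Carlo ensembles.

Runs freeze -> primary drying -> secondary drying with explicit state
handoff: primary drying starts uniformly at the freezing end temperature,
and secondary drying inherits the primary end-of-run temperature profile
together with the configured initial bound-water load.  Stage clocks are
stitched so the cycle summary reports cumulative times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cases import CaseSpec
from .config import ModelConfig, Protocol
from .freezing import FreezingResult, simulate_freezing
from .primary import PrimaryResult, simulate_primary
from .secondary import SecondaryResult, simulate_secondary

__all__ = ["CycleResult", "run_full_cycle", "monte_carlo_freezing"]


@dataclass
class CycleResult:
    """Per-stage results plus cycle-level summary scalars."""

    freezing: FreezingResult
    primary: PrimaryResult
    secondary: SecondaryResult
    summary: dict = field(default_factory=dict)
    handoff: dict = field(default_factory=dict)


def run_full_cycle(case: CaseSpec, seed: Optional[int] = None,
                   u: Optional[float] = None) -> CycleResult:
    """Simulate a complete continuous-lyophilization cycle for one vial.

    The freezing end state (temperature after the final cooling stage)
    seeds primary drying uniformly; the primary end temperature profile,
    interpolated onto the cake grid, seeds secondary drying.  Both
    handoffs are recorded and continuity is asserted.
    """
    cfg = cfg0 = case.config
    protos = case.protocols
    if not {"freezing", "primary", "secondary"} <= set(protos):
        raise ValueError("full cycle needs freezing, primary and secondary protocols")

    fz = simulate_freezing(cfg, protos["freezing"], mode=case.mode, seed=seed,
                           u=u, T0=case.T0_freezing)
    T_handoff1 = fz.final_state["T"]

    pr = simulate_primary(cfg, protos["primary"], T0=T_handoff1)

    # map the final frozen-layer profile onto the cake grid (the frozen
    # remnant at the end of primary drying is a thin, near-isothermal layer)
    n = cfg.numerics.n_z
    H = cfg.H
    S_end = (1.0 - cfg.numerics.front_end_fraction) * H
    z_frozen = S_end + np.linspace(0.0, 1.0, n) * (H - S_end)
    z_cake = np.linspace(0.0, H, n)
    T_handoff2 = np.interp(z_cake, z_frozen, pr.final_T)

    sec = simulate_secondary(cfg, protos["secondary"], T0=T_handoff2)

    assert abs(float(pr.summary["T_bottom"].iloc[0]) - T_handoff1) < 1e-9
    assert abs(float(sec.summary["T_bottom"].iloc[0]) - T_handoff2[-1]) < 1e-9

    t_freeze = fz.times.get("t_f5", fz.trajectory["t"].iloc[-1])
    summary = {
        **{k: float(v) for k, v in fz.times.items()},
        "t_freeze": float(t_freeze),
        "t_d1": float(pr.t_d1),
        "t_d2": float(sec.t_d2),
        "cycle_time": float(t_freeze + pr.t_d1 + sec.t_d2),
        "T_freeze_end": float(T_handoff1),
        "T_max_primary": float(pr.summary["T_max"].max()),
        "T_max_secondary": float(sec.summary["T_max"].max()),
        "final_c_w_mean": float(sec.summary["c_w_mean"].iloc[-1]),
        "evaporated_mass_visf": float(fz.evaporated_mass),
    }
    handoff = {"freezing_to_primary_T": float(T_handoff1),
               "primary_to_secondary_T": T_handoff2.tolist()}
    return CycleResult(freezing=fz, primary=pr, secondary=sec,
                       summary=summary, handoff=handoff)


def monte_carlo_freezing(cfg: ModelConfig, protocol: Protocol, mode: str,
                         n_runs: int, seed: int,
                         stop_after: str = "nucleation",
                         T0: float = 298.15) -> pd.DataFrame:
    """Ensemble of stochastic freezing runs with reproducible seeding.

    One root seed produces the per-run uniform draws; run ``i`` of an
    ensemble therefore nucleates exactly like a single
    :func:`~lyosim.freezing.simulate_freezing` call seeded with the same
    root when ``n_runs == 1``.

    Returns a data frame with one row per run: the uniform draw ``u``,
    the nucleation time and temperature, and (if the run continued past
    nucleation) the stage end times.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_runs):
        u = float(rng.random())
        res = simulate_freezing(cfg, protocol, mode=mode, u=u, T0=T0,
                                stop_after=stop_after)
        rows.append({"run": i, "u": u,
                     "t_nucleation": res.nucleation_time,
                     "T_nucleation": res.T_nucleation,
                     "T_fl": res.T_fl,
                     "m_i_n": res.m_i_n,
                     "t_f4": res.times.get("t_f4"),
                     "t_f5": res.times.get("t_f5"),
                     "completed": res.completed})
    return pd.DataFrame(rows)


def ensemble_stats(df: pd.DataFrame, column: str = "t_nucleation") -> dict:
    """Mean, standard deviation and quartiles of an ensemble output."""
    x = df[column].dropna().to_numpy(dtype=float)
    return {"n": int(x.size), "mean": float(np.mean(x)), "std": float(np.std(x, ddof=1)),
            "q25": float(np.quantile(x, 0.25)), "median": float(np.median(x)),
            "q75": float(np.quantile(x, 0.75))}
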