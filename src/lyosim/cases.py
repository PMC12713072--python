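"""Bundled scenario fixtures.

Each case returns a complete :class:`~lyosim.config.ModelConfig` plus the
per-stage ambient protocols and initial conditions for a documented study
scenario: the default full cycle, the single-step validation cases, the
VISF pressure study, the condenser-failure analysis, and the
thermal-gradient demonstration.  All values are set programmatically so a
scenario can be regenerated, inspected or perturbed from code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from .condenser import CondenserParams
from .config import ModelConfig, Protocol, Ramp

__all__ = ["CaseSpec", "make_case", "CASE_IDS", "default_protocols"]

HOUR = 3600.0
VISF_START = 0.25 * HOUR      # scheduled VISF start [s]
RAMP = 60.0                   # nominal ramp length for scheduled set-point moves [s]

CASE_IDS = ("default", "1", "2a", "2b", "3a", "3b", "visf-study",
            "condenser-failure", "gradient-demo")


@dataclass
class CaseSpec:
    """A runnable scenario: configuration, protocols and initial state."""

    name: str
    config: ModelConfig
    protocols: dict = field(default_factory=dict)   # stage -> Protocol
    mode: str = "visf-deterministic"                # freezing nucleation mode
    T0_freezing: float = 298.15
    T0_primary: float = 235.0
    T0_secondary: float = 273.0
    condenser: Optional[CondenserParams] = None
    notes: str = ""


def _freezing_protocol_default(visf_pressure: float = 1e4) -> Protocol:
    """Full-cycle freezing schedule: hold, then VISF set-point moves.

    Gas and surface temperatures drop when VISF starts and the chamber is
    evacuated from atmospheric pressure to the VISF pressure over one
    minute.
    """
    t1, t2 = VISF_START, VISF_START + RAMP
    return Protocol(
        T_b=Ramp.constant(270.0),                  # unused during freezing
        T_g=Ramp([t1, t2], [268.0, 230.0]),
        T_c=Ramp([t1, t2], [273.0, 240.0]),
        T_u=Ramp([t1, t2], [273.0, 240.0]),
        p_t=Ramp([t1, t2], [1e5, visf_pressure]),
        p_w_c=Ramp.constant(0.0),
        visf_start=VISF_START,
    )


def _primary_protocol_default() -> Protocol:
    return Protocol(T_b=Ramp.constant(270.0), T_g=Ramp.constant(230.0),
                    T_c=Ramp.constant(265.0), T_u=Ramp.constant(265.0),
                    p_t=Ramp.constant(10.0), p_w_c=Ramp.constant(3.0))


def _secondary_protocol_default() -> Protocol:
    return Protocol(T_b=Ramp.constant(295.0), T_g=Ramp.constant(290.0),
                    T_c=Ramp.constant(290.0), T_u=Ramp.constant(290.0),
                    p_t=Ramp.constant(10.0), p_w_c=Ramp.constant(3.0))


def default_protocols() -> dict:
    """The full-cycle stage protocols used by the ``default`` case."""
    return {"freezing": _freezing_protocol_default(),
            "primary": _primary_protocol_default(),
            "secondary": _secondary_protocol_default()}


def make_case(case_id: str, visf_pressure: float = 100.0) -> CaseSpec:
    """Build a bundled scenario by id.

    Parameters
    ----------
    case_id : str
        One of :data:`CASE_IDS`.
    visf_pressure : float
        Target chamber pressure for the ``visf-study`` case [Pa].
    """
    if case_id not in CASE_IDS:
        raise ValueError(f"unknown case {case_id!r}; valid ids: {', '.join(CASE_IDS)}")

    cfg = ModelConfig()

    if case_id == "default":
        return CaseSpec(name=case_id, config=cfg, protocols=default_protocols(),
                        mode="visf-deterministic",
                        notes="complete cycle with controlled nucleation at 268 K")

    if case_id == "1":
        # freezing-step validation: spontaneous nucleation at 263.18 K,
        # warmer walls, stronger film coefficients.  The measured gas
        # temperature trace is not bundled; a constant cold-gas hold that
        # reaches the nucleation temperature stands in (synthetic).
        cfg.transport.h_s1 = 7.0
        cfg.transport.h_s2 = 18.0
        cfg.transport.h_s3 = 15.0
        cfg.nucleation.T_n = 263.18
        proto = Protocol(T_g=Ramp.constant(258.0), T_c=Ramp.constant(272.0),
                         T_u=Ramp.constant(272.0), p_t=Ramp.constant(1e5),
                         p_w_c=Ramp.constant(0.0))
        return CaseSpec(name=case_id, config=cfg,
                        protocols={"freezing": proto},
                        mode="uncontrolled-deterministic", T0_freezing=280.0)

    if case_id in ("2a", "2b"):
        cfg.transport.h_b = 16.0
        cfg.transport.R_p1 = 3.4e7
        cfg.transport.R_p2 = 1.0
        T_b = 263.0 if case_id == "2a" else 313.0
        T0 = 231.0 if case_id == "2a" else 235.0
        proto = Protocol(T_b=Ramp.constant(T_b), T_g=Ramp.constant(230.0),
                         T_c=Ramp.constant(275.0), T_u=Ramp.constant(275.0),
                         p_t=Ramp.constant(10.0), p_w_c=Ramp.constant(3.0))
        return CaseSpec(name=case_id, config=cfg, protocols={"primary": proto},
                        T0_primary=T0)

    if case_id in ("3a", "3b"):
        cfg.formulation.V_l = 2e-6
        cfg.transport.h_b = 16.0
        cfg.desorption.f_a = 0.42
        cfg.desorption.E_a = 2.05e4
        cfg.desorption.c_w_0 = 0.088 if case_id == "3a" else 0.075
        proto = Protocol(T_b=Ramp.constant(293.0), T_g=Ramp.constant(285.0),
                         T_c=Ramp.constant(285.0), T_u=Ramp.constant(285.0),
                         p_t=Ramp.constant(10.0), p_w_c=Ramp.constant(3.0))
        return CaseSpec(name=case_id, config=cfg, protocols={"secondary": proto},
                        T0_secondary=273.0)

    if case_id == "visf-study":
        cfg.transport.h_s2 = 60.0
        cfg.transport.h_s3 = 60.0
        cfg.nucleation.T_n = 260.0
        t1, t2 = VISF_START, VISF_START + RAMP
        proto = Protocol(
            T_g=Ramp([t1, t2], [268.0, 260.0]),
            T_c=Ramp([t1, t2], [268.0, 260.0]),
            T_u=Ramp([t1, t2], [268.0, 260.0]),
            p_t=Ramp([t1, t2], [1e5, visf_pressure]),
            p_w_c=Ramp.constant(0.0),
            visf_start=VISF_START,
        )
        return CaseSpec(name=case_id, config=cfg, protocols={"freezing": proto},
                        mode="visf-deterministic", T0_freezing=280.0,
                        notes=f"VISF pressure study at {visf_pressure:g} Pa")

    if case_id == "condenser-failure":
        return CaseSpec(name=case_id, config=cfg,
                        protocols={"primary": _primary_protocol_default()},
                        condenser=CondenserParams(),
                        T0_primary=235.0,
                        notes="200 vials against an undersized condenser")

    # gradient-demo: thick, strongly heated sample for visible gradients.
    # Built on the validated primary-drying parameter set (low shelf
    # temperature, fitted cake resistance) with the film coefficient and
    # product height raised to exaggerate the vertical gradient.
    cfg.transport.h_b = 30.0
    cfg.transport.R_p1 = 3.4e7
    cfg.transport.R_p2 = 1.0
    cfg.H_override = 0.02
    proto = Protocol(T_b=Ramp.constant(263.0), T_g=Ramp.constant(230.0),
                     T_c=Ramp.constant(275.0), T_u=Ramp.constant(275.0),
                     p_t=Ramp.constant(10.0), p_w_c=Ramp.constant(3.0))
    return CaseSpec(name="gradient-demo", config=cfg,
                    protocols={"primary": proto},
                    T0_primary=231.0,
                    notes="thick sample / strong bottom heating")


def case_to_dict(case: CaseSpec) -> dict:
    """Serializable form of a case (used by config read/write)."""
    d = {"name": case.name, "config": case.config.to_dict(),
         "protocols": {k: v.to_dict() for k, v in case.protocols.items()},
         "mode": case.mode, "T0_freezing": case.T0_freezing,
         "T0_primary": case.T0_primary, "T0_secondary": case.T0_secondary,
         "notes": case.notes}
    if case.condenser is not None:
        d["condenser"] = dataclasses.asdict(case.condenser)
    return d


def case_from_dict(d: dict) -> CaseSpec:
    cond = d.get("condenser")
    return CaseSpec(
        name=d.get("name", "custom"),
        config=ModelConfig.from_dict(d.get("config", {})),
        protocols={k: Protocol.from_dict(v) for k, v in d.get("protocols", {}).items()},
        mode=d.get("mode", "visf-deterministic"),
        T0_freezing=d.get("T0_freezing", 298.15),
        T0_primary=d.get("T0_primary", 235.0),
        T0_secondary=d.get("T0_secondary", 273.0),
        condenser=CondenserParams(**cond) if cond else None,
        notes=d.get("notes", ""),
    )
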