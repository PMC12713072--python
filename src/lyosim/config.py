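"""Model parameters, derived formulation quantities, and operating protocols.

The simulator describes a single suspended glass vial moving through a
continuous lyophilizer.  Everything the physics modules need is collected
here: the formulation (fill volume and solute fraction), the vial geometry,
thermophysical constants, heat/mass-transfer parameters, desorption and
nucleation kinetics, numerical settings, and the time-dependent ambient
protocol (shelf/gas/wall temperatures and chamber pressures).

Two small derivations connect the user-facing formulation inputs to the
quantities the solvers use:

* additive-volume mixing splits the fill volume into solute and water
  masses, ``m_l = V_l / ((1 - x_s)/rho_w + x_s/rho_s)``;
* the frozen-product geometry converts those masses into the frozen
  volume, height and density, ``V_f = m_w0/rho_i + m_s/rho_s``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Stefan-Boltzmann constant [W m^-2 K^-4]
SIGMA = 5.67e-8
#: universal gas constant [J mol^-1 K^-1]
R_GAS = 8.314


class InvalidParameterError(ValueError):
    """A physically inadmissible parameter combination."""


def derive_formulation_masses(V_l: float, x_s: float, rho_w: float = 1000.0,
                              rho_s: float = 1587.9) -> tuple[float, float, float]:
    """Split a liquid fill into total, solute and water masses.

    Uses additive-volume mixing: the solute and water volumes are assumed
    to add to the fill volume, so the total liquid mass is
    ``m_l = V_l / ((1 - x_s)/rho_w + x_s/rho_s)``.

    Parameters
    ----------
    V_l : float
        Fill volume [m^3].
    x_s : float
        Solute mass fraction, ``0 <= x_s < 1``.
    rho_w, rho_s : float
        Densities of liquid water and solute [kg m^-3].

    Returns
    -------
    (m_l, m_s, m_w0) : tuple of float
        Total liquid, solute and initial water mass [kg].
    """
    if not (0.0 <= x_s < 1.0):
        raise InvalidParameterError(f"solute mass fraction must be in [0, 1), got {x_s}")
    if V_l <= 0 or rho_w <= 0 or rho_s <= 0:
        raise InvalidParameterError("fill volume and densities must be positive")
    m_l = V_l / ((1.0 - x_s) / rho_w + x_s / rho_s)
    m_s = x_s * m_l
    m_w0 = (1.0 - x_s) * m_l
    return m_l, m_s, m_w0


def frozen_geometry(m_w0: float, m_s: float, rho_i: float = 917.0,
                    rho_s: float = 1587.9, d: float = 0.024) -> tuple[float, float, float]:
    """Frozen-product volume, height and density for a cylindrical fill.

    All free water is taken as ice, so ``V_f = m_w0/rho_i + m_s/rho_s``,
    the height is ``H = V_f / A_z`` and the frozen density is the total
    mass over the frozen volume.

    Returns
    -------
    (V_f, H, rho_f) : tuple of float
        Frozen volume [m^3], product height [m], frozen density [kg m^-3].
    """
    if m_w0 < 0 or m_s < 0:
        raise InvalidParameterError("masses must be nonnegative")
    if m_w0 + m_s == 0:
        raise InvalidParameterError("total mass must be positive")
    if d <= 0:
        raise InvalidParameterError("vial diameter must be positive")
    V_f = m_w0 / rho_i + m_s / rho_s
    A_z = np.pi * d ** 2 / 4.0
    H = V_f / A_z
    rho_f = (m_w0 + m_s) / V_f
    return V_f, H, rho_f


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class Formulation:
    """Liquid formulation in the vial (sucrose in water by default)."""

    V_l: float = 3e-6          # fill volume [m^3]
    x_s: float = 0.05          # solute mass fraction [-]
    rho_w: float = 1000.0      # liquid water density [kg m^-3]
    rho_s: float = 1587.9      # solute density [kg m^-3]
    rho_i: float = 917.0       # ice density [kg m^-3]
    M_s: float = 0.3423        # solute molar mass [kg mol^-1]
    M_w: float = 0.018         # water molar mass [kg mol^-1]
    M_in: float = 0.028        # inert-gas (N2) molar mass [kg mol^-1]
    K_f: float = 1.86          # molal freezing-point-depression constant [kg K mol^-1]
    T_f_w: float = 273.15      # freezing point of pure water [K]

    def __post_init__(self):
        if not (0.0 <= self.x_s < 1.0):
            raise InvalidParameterError("x_s must be in [0, 1)")
        if min(self.V_l, self.rho_w, self.rho_s, self.rho_i) <= 0:
            raise InvalidParameterError("V_l and densities must be positive")

    @property
    def masses(self) -> tuple[float, float, float]:
        """(m_l, m_s, m_w0) from additive-volume mixing."""
        return derive_formulation_masses(self.V_l, self.x_s, self.rho_w, self.rho_s)


@dataclass
class Vial:
    """Cylindrical vial geometry (10R vial by default)."""

    d: float = 0.024           # inner diameter [m]
    eps_gl: float = 0.8        # glass emissivity [-]

    @property
    def A_z(self) -> float:
        """Cross-sectional area [m^2]."""
        return np.pi * self.d ** 2 / 4.0

    @property
    def r_o(self) -> float:
        """Inner radius [m]."""
        return self.d / 2.0

    def A_r(self, h: float) -> float:
        """Side (lateral) area for product height ``h`` [m^2]."""
        return np.pi * self.d * h


@dataclass
class Thermo:
    """Constant thermophysical properties.

    Subscripts: s solute, w liquid water, i ice, f frozen product,
    e effective dried cake (solid + gas in pores), d dried solid.
    """

    C_p_s: float = 1204.0
    C_p_w: float = 4187.0      # J kg^-1 K^-1 (SI; some tables print kJ-based values)
    C_p_i: float = 2108.0
    C_p_f: float = 2163.0
    C_p_e: float = 2590.0
    k_s: float = 0.126
    k_w: float = 0.598
    k_i: float = 2.25
    k_f: float = 2.07
    k_e: float = 0.217
    rho_e: float = 215.0
    rho_d: float = 212.21
    dH_fus: float = 3.34e5     # heat of fusion [J kg^-1]
    dH_sub: float = 2.84e6     # heat of sublimation [J kg^-1]
    dH_des: float = 2.68e6     # heat of desorption [J kg^-1]


@dataclass
class Transport:
    """Heat/mass-transfer coefficients, radiation factors, cake resistance."""

    h_s1: float = 5.0          # top convection [W m^-2 K^-1]
    h_s2: float = 10.0         # bottom convection (freezing) [W m^-2 K^-1]
    h_s3: float = 8.0          # side convection [W m^-2 K^-1]
    h_b: float = 15.0          # bottom coefficient in drying [W m^-2 K^-1]
    h_m: float = 6.34e-3       # evaporation mass-transfer coefficient [kg m^-2 s^-1]
    F_s1: float = 0.8          # top radiation transfer factor [-]
    F_s3: float = 0.624        # side radiation transfer factor [-]
    R_p0: float = 1.5e4        # cake resistance, constant term [m s^-1]
    R_p1: float = 3.0e7        # cake resistance, saturating term [s^-1]
    R_p2: float = 10.0         # cake resistance, half-saturation thickness [m]


@dataclass
class NucleationKinetics:
    """Ice-nucleation trigger.

    ``T_n`` is the deterministic nucleation temperature.  For stochastic
    nucleation the first-nucleus rate is a Poisson intensity
    ``lambda = k_n (T_f,l - T)^b_n V_l``; ``k_n`` and ``b_n`` have no
    defaults and must be supplied to run a stochastic simulation.
    """

    T_n: float = 268.0
    k_n: Optional[float] = None    # [m^-3 s^-1 K^-b_n]
    b_n: Optional[float] = None    # [-]

    def require_stochastic(self):
        if self.k_n is None or self.b_n is None:
            raise InvalidParameterError(
                "stochastic nucleation requires k_n and b_n (no defaults are provided)")
        if self.k_n < 0 or self.b_n < 0:
            raise InvalidParameterError("k_n and b_n must be nonnegative")


@dataclass
class Desorption:
    """Linear-driving-force desorption kinetics with Arrhenius rate."""

    f_a: float = 1.5e-3        # frequency factor [s^-1]
    E_a: float = 6500.0        # activation energy [J mol^-1]
    c_w_0: float = 0.088       # initial bound water [kg/kg solid]
    c_w_inf: float = 0.01      # target residual moisture [kg/kg solid]
    c_w_eq: float = 0.0        # equilibrium concentration [kg/kg solid]


@dataclass
class Numerics:
    """Grid size, solver tolerances and event handling."""

    n_z: int = 25              # grid points in the 1-D drying models
    rtol: float = 1e-6
    atol: float = 1e-8
    front_floor: float = 1e-6      # S(t0) = front_floor * H
    front_end_fraction: float = 1e-4   # stop primary drying at S = (1 - frac) H
    solid_fraction_end: float = 0.95   # solidification ends at m_i = frac * m_w(t_f3)
    cooling_target: float = 235.0      # final-cooling stage target temperature [K]
    max_time: float = 3.6e5            # per-stage integration horizon [s]


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass
class Ambient:
    """Ambient conditions at one instant."""

    T_b: float   # bottom shelf temperature [K]
    T_g: float   # gas temperature [K]
    T_c: float   # chamber wall temperature [K]
    T_u: float   # upper chamber surface temperature [K]
    p_t: float   # total pressure [Pa]
    p_w_c: float  # chamber water partial pressure [Pa]


class Ramp:
    """Piecewise-linear function of time with constant extrapolation.

    Breakpoint times must be strictly increasing; evaluation outside the
    breakpoint range clamps to the endpoint values.
    """

    def __init__(self, times, values):
        t = np.atleast_1d(np.asarray(times, dtype=float))
        v = np.atleast_1d(np.asarray(values, dtype=float))
        if t.shape != v.shape:
            raise InvalidParameterError("times and values must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("breakpoint times must be strictly increasing")
        self.times = t
        self.values = v

    @classmethod
    def constant(cls, value: float) -> "Ramp":
        return cls([0.0], [value])

    def __call__(self, t):
        return np.interp(t, self.times, self.values)

    def to_dict(self):
        return {"t": self.times.tolist(), "v": self.values.tolist()}

    @classmethod
    def from_dict(cls, d):
        if isinstance(d, (int, float)):
            return cls.constant(float(d))
        return cls(d["t"], d["v"])

    def __eq__(self, other):
        return (isinstance(other, Ramp)
                and np.array_equal(self.times, other.times)
                and np.array_equal(self.values, other.values))


@dataclass
class Protocol:
    """Time-dependent ambient conditions for one processing stage."""

    T_b: Ramp = field(default_factory=lambda: Ramp.constant(270.0))
    T_g: Ramp = field(default_factory=lambda: Ramp.constant(268.0))
    T_c: Ramp = field(default_factory=lambda: Ramp.constant(273.0))
    T_u: Ramp = field(default_factory=lambda: Ramp.constant(273.0))
    p_t: Ramp = field(default_factory=lambda: Ramp.constant(1e5))
    p_w_c: Ramp = field(default_factory=lambda: Ramp.constant(0.0))
    visf_start: Optional[float] = None   # scheduled VISF start time [s]

    def __call__(self, t: float) -> Ambient:
        return Ambient(T_b=float(self.T_b(t)), T_g=float(self.T_g(t)),
                       T_c=float(self.T_c(t)), T_u=float(self.T_u(t)),
                       p_t=float(self.p_t(t)), p_w_c=float(self.p_w_c(t)))

    def to_dict(self):
        d = {k: getattr(self, k).to_dict()
             for k in ("T_b", "T_g", "T_c", "T_u", "p_t", "p_w_c")}
        d["visf_start"] = self.visf_start
        return d

    @classmethod
    def from_dict(cls, d):
        kw = {k: Ramp.from_dict(d[k]) for k in ("T_b", "T_g", "T_c", "T_u", "p_t", "p_w_c") if k in d}
        return cls(visf_start=d.get("visf_start"), **kw)


def eval_protocol(protocol: Protocol, t: float) -> Ambient:
    """Evaluate all protocol channels at time ``t`` (clamped interpolation)."""
    return protocol(t)


def step_ramp(t_step: float, before: float, after: float,
              ramp_seconds: float = 1.0) -> Ramp:
    """A nominal step change modeled as a short linear ramp.

    Keeps right-hand sides continuous for the stiff integrators; the default
    1 s ramp is negligible against process timescales of minutes to hours.
    """
    return Ramp([t_step, t_step + ramp_seconds], [before, after])


# ---------------------------------------------------------------------------
# top-level configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Complete parameterization of the single-vial lyophilization model.

    Derived quantities (masses, frozen geometry) are recomputed from the
    formulation on access so that overriding a primitive parameter stays
    consistent.  ``H_override`` replaces the derived product height for
    standalone drying studies of a thicker sample; the frozen density is
    then kept at its derived value.
    """

    formulation: Formulation = field(default_factory=Formulation)
    vial: Vial = field(default_factory=Vial)
    thermo: Thermo = field(default_factory=Thermo)
    transport: Transport = field(default_factory=Transport)
    nucleation: NucleationKinetics = field(default_factory=NucleationKinetics)
    desorption: Desorption = field(default_factory=Desorption)
    numerics: Numerics = field(default_factory=Numerics)
    H_override: Optional[float] = None

    # ---- derived formulation/geometry ------------------------------------
    @property
    def m_l(self) -> float:
        return self.formulation.masses[0]

    @property
    def m_s(self) -> float:
        return self.formulation.masses[1]

    @property
    def m_w0(self) -> float:
        return self.formulation.masses[2]

    @property
    def V_f(self) -> float:
        return frozen_geometry(self.m_w0, self.m_s, self.formulation.rho_i,
                               self.formulation.rho_s, self.vial.d)[0]

    @property
    def H(self) -> float:
        if self.H_override is not None:
            return self.H_override
        return frozen_geometry(self.m_w0, self.m_s, self.formulation.rho_i,
                               self.formulation.rho_s, self.vial.d)[1]

    @property
    def rho_f(self) -> float:
        return frozen_geometry(self.m_w0, self.m_s, self.formulation.rho_i,
                               self.formulation.rho_s, self.vial.d)[2]

    @property
    def fill_height(self) -> float:
        """Initial liquid fill height [m]."""
        return self.formulation.V_l / self.vial.A_z

    # ---- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "formulation": dataclasses.asdict(self.formulation),
            "vial": dataclasses.asdict(self.vial),
            "thermo": dataclasses.asdict(self.thermo),
            "transport": dataclasses.asdict(self.transport),
            "nucleation": dataclasses.asdict(self.nucleation),
            "desorption": dataclasses.asdict(self.desorption),
            "numerics": dataclasses.asdict(self.numerics),
            "H_override": self.H_override,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            formulation=Formulation(**d.get("formulation", {})),
            vial=Vial(**d.get("vial", {})),
            thermo=Thermo(**d.get("thermo", {})),
            transport=Transport(**d.get("transport", {})),
            nucleation=NucleationKinetics(**d.get("nucleation", {})),
            desorption=Desorption(**d.get("desorption", {})),
            numerics=Numerics(**d.get("numerics", {})),
            H_override=d.get("H_override"),
        )
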