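"""Radiative and convective heat-transfer primitives shared by all stages.

Radiation between gray diffuse surfaces is expressed through a transfer
factor ``F`` such that the net heat received by surface 1 is
``Q = sigma * A1 * F * (T2**4 - T1**4)``.  For two surfaces forming an
enclosure the factor follows from the emissivities, areas and view factor;
it is always bounded above by the emissivity of the receiving surface.

During freezing the growing ice layer acts as an extra conduction
resistance in series with the surface film, which is expressed through
overall coefficients for the flat bottom and the cylindrical side shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SIGMA, InvalidParameterError


@dataclass
class SurfaceHeatLoads:
    """Heat-flow rates into the product at the top, bottom and side [W]."""

    Q_s1: float
    Q_s2: float
    Q_s3: float

    @property
    def total(self) -> float:
        return self.Q_s1 + self.Q_s2 + self.Q_s3


def transfer_factor_enclosure(eps1: float, eps2: float, A1: float, A2: float,
                              F12: float) -> float:
    """Gray-body transfer factor for two surfaces forming an enclosure.

    Returns ``F`` such that ``Q = sigma A1 F (T2^4 - T1^4)``:

    ``F = 1 / [(1-eps1)/eps1 + 1/F12 + (1-eps2)/eps2 * A1/A2]``

    In the limit of a small surface enclosed by a large one (``F12 = 1``,
    ``A2 >> A1``) this reduces to ``F = eps1``.
    """
    if eps1 <= 0 or eps2 <= 0:
        raise InvalidParameterError("emissivities must be positive")
    if eps1 > 1 or eps2 > 1:
        raise InvalidParameterError("emissivities cannot exceed 1")
    if A1 <= 0 or A2 <= 0:
        raise InvalidParameterError("areas must be positive")
    if not (0 <= F12 <= 1):
        raise InvalidParameterError("view factor must be in [0, 1]")
    denom = (1 - eps1) / eps1 + 1.0 / F12 + (1 - eps2) / eps2 * (A1 / A2)
    return 1.0 / denom


def radiative_heat(F: float, A: float, T_s: float, T_env: float) -> float:
    """Net radiant power received by a surface at ``T_s`` from ``T_env`` [W]."""
    if T_s <= 0 or T_env <= 0:
        raise InvalidParameterError("absolute temperatures must be positive")
    return SIGMA * A * F * (T_env ** 4 - T_s ** 4)


def linearized_h_rad(F: float, T_ref: float) -> float:
    """Radiation written as Newton's law of cooling: ``h = 4 sigma F T_ref^3``.

    ``T_ref`` should be the arithmetic mean of the two surface temperatures.
    """
    if T_ref <= 0:
        raise InvalidParameterError("reference temperature must be positive")
    return 4.0 * SIGMA * F * T_ref ** 3


def linearization_error(T_base: float, dT: float) -> float:
    """Relative error of the linearized radiation law for the pair
    ``(T_base, T_base + dT)``, with the mean temperature as reference.

    Around 300 K the error is ~0.1% for a 20 K difference and ~2% for a
    100 K difference, which justifies folding radiation into convective
    coefficients in the lumped freezing model.
    """
    if dT == 0:
        return 0.0
    T2 = T_base + dT
    exact = T2 ** 4 - T_base ** 4
    linear = 4.0 * ((T_base + T2) / 2.0) ** 3 * dT
    return abs(exact - linear) / abs(exact)


def overall_U_bottom(h_s2: float, l: float, k_i: float) -> float:
    """Overall coefficient through a flat ice layer of thickness ``l``.

    Series resistance of the surface film and the slab:
    ``U = 1 / (1/h_s2 + l/k_i)``.
    """
    if h_s2 <= 0:
        raise InvalidParameterError("h_s2 must be positive")
    if l < 0:
        raise InvalidParameterError("ice thickness must be nonnegative")
    return 1.0 / (1.0 / h_s2 + l / k_i)


def overall_U_side(h_s3: float, r: float, r_o: float, k_i: float) -> float:
    """Overall coefficient through a cylindrical ice shell, referenced to
    the outer surface area: ``U = 1 / (1/h_s3 + r_o ln(r_o/r)/k_i)``.
    """
    if h_s3 <= 0:
        raise InvalidParameterError("h_s3 must be positive")
    if r <= 0 or r > r_o:
        raise InvalidParameterError("need 0 < r <= r_o")
    return 1.0 / (1.0 / h_s3 + r_o * np.log(r_o / r) / k_i)


def surface_heat_loads(T: float, amb, A_z: float, A_r: float, transport,
                       U_s2: float | None = None,
                       U_s3: float | None = None) -> SurfaceHeatLoads:
    """Heat loads on the three vial surfaces for the lumped freezing model.

    Top and bottom use Newton's law with coefficients that already fold in
    linearized radiation; the side combines convection from the gas with
    fourth-power radiation from the chamber wall.  When an ice layer is
    present, ``U_s2``/``U_s3`` replace the bare film coefficients.
    """
    h2 = transport.h_s2 if U_s2 is None else U_s2
    h3 = transport.h_s3 if U_s3 is None else U_s3
    Q1 = transport.h_s1 * A_z * (amb.T_u - T)
    Q2 = h2 * A_z * (amb.T_g - T)
    Q3 = h3 * A_r * (amb.T_g - T) + SIGMA * A_r * transport.F_s3 * (amb.T_c ** 4 - T ** 4)
    return SurfaceHeatLoads(Q1, Q2, Q3)
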