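"""Soil aeration metrics and growing-degree-day sums.

Water-filled pore space (WFPS) and the relative gas diffusion
coefficient Dp/D0 are the two standard proxies for soil O2 status used
to interpret N2O emission dynamics. Dp/D0 follows the Moldrup-type
water-retention model

    Dp/D0 = Phi^2 * (eps/Phi)^X,
    X = 2 + log(eps100^0.25) / log(eps100/Phi),

where Phi is total porosity, eps the volumetric air content, and eps100
the air content at -100 cm H2O matric potential (all m3 m-3). The
logarithm base cancels in the ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SoilState",
    "total_porosity",
    "wfps",
    "relative_gas_diffusivity",
    "growing_degree_days",
    "soil_state",
]

DEFAULT_PARTICLE_DENSITY = 2.65  # g cm-3, standard mineral-soil value


def total_porosity(rho_b: float, rho_s: float = DEFAULT_PARTICLE_DENSITY) -> float:
    """Phi = 1 - rho_b / rho_s (m3 m-3)."""
    if rho_b <= 0 or rho_s <= 0:
        raise ValueError("densities must be positive")
    if rho_b >= rho_s:
        raise ValueError("bulk density must be below particle density")
    return 1.0 - rho_b / rho_s


def wfps(theta_g: float, rho_b: float, rho_s: float = DEFAULT_PARTICLE_DENSITY) -> float:
    """Water-filled pore space from gravimetric water and bulk density.

    theta_v = theta_g * rho_b (water density 1 g cm-3); wfps = theta_v /
    Phi, clipped to [0, 1] with a warning when measurement error pushes
    it outside.
    """
    if theta_g < 0:
        raise ValueError("gravimetric water content must be non-negative")
    phi = total_porosity(rho_b, rho_s)
    theta_v = theta_g * rho_b
    value = theta_v / phi
    if value > 1.0:
        warnings.warn(f"WFPS {value:.3f} > 1 clipped to 1 (theta_v exceeds porosity)")
        value = 1.0
    return value


def relative_gas_diffusivity(phi: float, epsilon: float, epsilon100: float) -> float:
    """Relative gas diffusion coefficient Dp/D0 (dimensionless, in [0, Phi^2])."""
    if not 0 < phi < 1:
        raise ValueError("total porosity must lie in (0, 1)")
    if not 0 <= epsilon <= phi:
        raise ValueError("air content must lie in [0, porosity]")
    if not 0 < epsilon100 < phi:
        if math.isclose(epsilon100, phi):
            raise ZeroDivisionError(
                "epsilon100 equals porosity: the exponent's denominator log(eps100/Phi) is zero"
            )
        raise ValueError("epsilon100 must lie in (0, porosity)")
    x = 2.0 + math.log(epsilon100**0.25) / math.log(epsilon100 / phi)
    if epsilon == 0:
        return 0.0
    return phi**2 * (epsilon / phi) ** x


def growing_degree_days(daily_mean_temps, t_base: float = 0.0) -> float:
    """Degree-day sum: sum of max(0, T_mean - t_base) over days.

    The base temperature is an assumption of the analysis (default 0 C);
    crop-specific conventions differ, so it is exposed as a parameter.
    """
    t = np.asarray(daily_mean_temps, dtype=float)
    if t.size == 0:
        raise ValueError("temperature series must be non-empty")
    return float(np.sum(np.clip(t - t_base, 0.0, None)))


@dataclass
class SoilState:
    """Aeration state of one plot on one sampling day."""

    theta_g: float  # gravimetric water, g g-1
    rho_b: float  # dry bulk density, g cm-3
    rho_s: float  # particle density, g cm-3
    phi: float  # total porosity, m3 m-3
    epsilon: float  # volumetric air content, m3 m-3
    epsilon100: float  # air content at -100 cm H2O, m3 m-3
    wfps: float  # fraction
    dp_d0: float  # relative diffusivity


def soil_state(
    theta_g: float,
    rho_b: float,
    epsilon100: float,
    rho_s: float = DEFAULT_PARTICLE_DENSITY,
) -> SoilState:
    """Derive the full aeration state from field measurements."""
    phi = total_porosity(rho_b, rho_s)
    w = wfps(theta_g, rho_b, rho_s)
    epsilon = phi * (1.0 - w)
    return SoilState(
        theta_g=theta_g,
        rho_b=rho_b,
        rho_s=rho_s,
        phi=phi,
        epsilon=epsilon,
        epsilon100=epsilon100,
        wfps=w,
        dp_d0=relative_gas_diffusivity(phi, epsilon, epsilon100),
    )
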