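"""Dynamic-light-scattering and electrophoresis reductions, and the mapping
between the zeta potential (measured at the hydrodynamic shear plane) and the
membrane surface potential through the decaying diffuse-layer profile.

For a planar 1:1 double layer the Gouy-Chapman potential profile gives

    tanh(zeta~/4) = tanh(psi~/4) * exp(-kappa * x)

with reduced potentials psi~ = e psi / kB T and x the shear-plane distance.
Measuring zeta at several ionic strengths and regressing
ln[tanh(zeta~/4)/tanh(psi~/4)] on kappa (through the origin) estimates x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import EPS0, thermal_voltage
from .electro import SolutionConditions, debye_kappa

__all__ = [
    "ZetaPoint",
    "ShearPlane",
    "hydrodynamic_diameter",
    "zeta_from_mobility",
    "zeta_from_surface",
    "surface_from_zeta",
    "estimate_shear_plane",
]


@dataclass(frozen=True)
class ZetaPoint:
    """One zeta-titration point at peptide-to-outer-leaflet-lipid ratio."""

    P_over_L_half: float
    zeta: float  # V
    DH: float | None = None  # m, vesicle hydrodynamic diameter

    def __post_init__(self) -> None:
        if self.P_over_L_half < 0:
            raise ValueError("P_over_L_half must be non-negative")


@dataclass
class ShearPlane:
    x: float  # m
    x_sd: float
    residuals: np.ndarray = field(repr=False)
    n_points: int = 0


def hydrodynamic_diameter(D: float, temperature: float = 298.15, eta: float = 8.9e-4) -> float:
    """Stokes-Einstein hydrodynamic diameter DH = kB T / (3 pi eta D) (m)."""
    if D <= 0 or eta <= 0:
        raise ValueError("diffusion coefficient and viscosity must be positive")
    from .constants import K_BOLTZMANN

    return K_BOLTZMANN * temperature / (3.0 * math.pi * eta * D)


def zeta_from_mobility(
    mu: float, eta_w: float = 8.9e-4, eps_r: float = 78.5, f_kR: float = 1.5
) -> float:
    """Henry relation zeta = 3 mu eta_w / (2 eps_r eps0 f(kR)) (V).

    f_kR = 1.5 is the Smoluchowski limit (large vesicle vs Debye length),
    where this reduces to zeta = mu eta / (eps_r eps0).
    """
    if f_kR <= 0:
        raise ValueError("f_kR must be positive")
    return 3.0 * mu * eta_w / (2.0 * eps_r * EPS0 * f_kR)


def _reduced(psi: float, temperature: float) -> float:
    return psi / thermal_voltage(temperature)


def zeta_from_surface(
    psi: float, kappa: float, x: float, temperature: float = 298.15
) -> float:
    """Potential at distance x from the surface (the zeta potential when x is
    the shear-plane position), from the planar Gouy-Chapman profile."""
    if abs(psi) >= 0.4:
        raise ValueError("|psi| outside the 0.4 V sanity bound")
    t = math.tanh(_reduced(psi, temperature) / 4.0) * math.exp(-kappa * x)
    return 4.0 * math.atanh(t) * thermal_voltage(temperature)


def surface_from_zeta(
    zeta: float, kappa: float, x: float, temperature: float = 298.15
) -> float:
    """Invert the profile: surface potential from zeta measured at distance x."""
    t = math.tanh(_reduced(zeta, temperature) / 4.0) * math.exp(kappa * x)
    if abs(t) >= 1.0:
        raise ValueError(
            "zeta too large for the stated kappa*x: tanh argument outside (-1, 1)"
        )
    return 4.0 * math.atanh(t) * thermal_voltage(temperature)


def estimate_shear_plane(
    pairs: Sequence[tuple[float, float, float]], temperature: float = 298.15
) -> ShearPlane:
    """Shear-plane distance from (zeta, psi, kappa) triplets at >= 2 ionic
    strengths: regression of ln[tanh(zeta~/4)/tanh(psi~/4)] on kappa, forced
    through the origin (at kappa -> 0 the ratio is 1), slope = -x."""
    if len(pairs) < 2:
        raise ValueError("need zeta/psi pairs at >= 2 ionic strengths")
    Vt = thermal_voltage(temperature)
    kap = np.array([p[2] for p in pairs], dtype=float)
    y = np.empty(len(pairs))
    for i, (zeta, psi, _) in enumerate(pairs):
        tz = math.tanh(zeta / Vt / 4.0)
        tp = math.tanh(psi / Vt / 4.0)
        if tz * tp <= 0:
            raise ValueError("zeta and psi must have the same sign")
        y[i] = math.log(tz / tp)
    # through-origin least squares: y = -x * kappa
    skk = float(kap @ kap)
    x = -float(kap @ y) / skk
    resid = y + x * kap
    dof = max(len(pairs) - 1, 1)
    x_sd = math.sqrt(float(resid @ resid) / dof / skk)
    return ShearPlane(x=x, x_sd=x_sd, residuals=resid, n_points=len(pairs))
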