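"""Planar double-layer electrostatics: Debye screening, the Grahame relation,
membrane surface charge with bound sodium, and the surface-potential solver.

The membrane is treated as an infinite charged plane in a symmetric 1:1
electrolyte (Gouy-Chapman theory). Its bare charge comes from the anionic
lipid fraction, partially neutralized by sodium bound to the headgroups with
an intrinsic binding constant, and shifted by adsorbed peptide charge. The
surface potential is the root of (lipid surface charge density) = (diffuse
double-layer charge density from the Grahame equation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .constants import (
    E_CHARGE,
    EPS0,
    FARADAY,
    K_BOLTZMANN,
    N_AVOGADRO,
    R_GAS,
    ph_shift_per_volt,
    thermal_voltage,
)

__all__ = [
    "SolutionConditions",
    "MembraneSpec",
    "debye_kappa",
    "grahame_sigma",
    "grahame_sigma_linearized",
    "lipid_sigma",
    "solve_surface_potential",
    "surface_pH",
    "boltzmann_surface_conc",
]

#: root bracket for the surface potential, volts
PSI_BRACKET = (-0.300, 0.300)
#: absolute tolerance on the surface potential root, volts (1e-6 mV)
PSI_XTOL = 1e-9


@dataclass(frozen=True)
class SolutionConditions:
    """Bulk aqueous phase: pH, temperature, 1:1 salt, relative permittivity."""

    pH_bulk: float
    temperature: float = 298.15  # K
    c_salt: float = 0.150  # mol/L monovalent salt (CNa)
    eps_r: float = 78.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.pH_bulk <= 14.0:
            raise ValueError(f"pH_bulk must be in [0, 14], got {self.pH_bulk}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.c_salt <= 0:
            raise ValueError("c_salt must be positive (mol/L)")
        if self.eps_r <= 0:
            raise ValueError("eps_r must be positive")


@dataclass(frozen=True)
class MembraneSpec:
    """Planar bilayer leaflet: anionic fraction, area per lipid, Na+ binding.

    Parameters
    ----------
    XA : anionic lipid mole fraction (0.3 for 7POPC:3POPG).
    AL_A2 : area per lipid in Angstrom^2. Default 70, a standard value for
        fluid POPC/POPG leaflets; with XA=0.3, KNa=0.6 /M and 150 mM salt it
        places the bare-membrane surface potential at -47 mV.
    KNa : intrinsic sodium binding constant, 1/M. The bound-sodium fraction
        is XNa = KNa * c_salt (bulk concentration, no Boltzmann enhancement).
    """

    XA: float = 0.3
    AL_A2: float = 70.0
    KNa: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.XA <= 1.0:
            raise ValueError("XA must be in [0, 1]")
        if self.AL_A2 <= 0:
            raise ValueError("AL_A2 must be positive")
        if self.KNa < 0:
            raise ValueError("KNa must be non-negative")

    @property
    def AL_m2(self) -> float:
        """Area per lipid in m^2."""
        return self.AL_A2 * 1e-20


def debye_kappa(solution: SolutionConditions) -> float:
    """Inverse Debye length kappa (1/m) for a 1:1 electrolyte.

    kappa^2 = 2e3 * NA * e^2 * c_salt / (eps0 * eps_r * kB * T);
    at 150 mM, 25 C in water 1/kappa is about 7.9 A.
    """
    num = 2.0 * 1000.0 * N_AVOGADRO * E_CHARGE**2 * solution.c_salt
    den = EPS0 * solution.eps_r * K_BOLTZMANN * solution.temperature
    return math.sqrt(num / den)


def grahame_sigma(psi: float, solution: SolutionConditions) -> float:
    """Diffuse-layer charge density (C/m^2) at surface potential psi (V).

    Grahame equation for a symmetric 1:1 electrolyte:
        sigma = sqrt(8000 eps0 eps_r R T c_salt) * sinh(e psi / (2 kB T))
    Odd in psi; reduces to eps0*eps_r*kappa*psi for small potentials.
    """
    if abs(psi) >= 0.5:
        raise ValueError(f"|psi| = {abs(psi):.3f} V outside sanity bound 0.5 V")
    pref = math.sqrt(
        8000.0 * EPS0 * solution.eps_r * R_GAS * solution.temperature * solution.c_salt
    )
    return pref * math.sinh(psi / (2.0 * thermal_voltage(solution.temperature)))


def grahame_sigma_linearized(psi: float, solution: SolutionConditions) -> float:
    """Debye-Hueckel limit of the Grahame relation: eps0*eps_r*kappa*psi."""
    return EPS0 * solution.eps_r * debye_kappa(solution) * psi


def lipid_sigma(
    membrane: MembraneSpec,
    solution: SolutionConditions,
    Xb: float = 0.0,
    zp: float = 0.0,
) -> float:
    """Membrane surface charge density (C/m^2) with bound Na+ and peptide.

    sigma = (e / AL) * (-XA + XNa + Xb * zp), with XNa = KNa * c_salt.
    Xb is adsorbed peptide per outer-leaflet lipid, zp its net charge.
    """
    if Xb < 0:
        raise ValueError("Xb must be non-negative")
    XNa = membrane.KNa * solution.c_salt
    return (E_CHARGE / membrane.AL_m2) * (-membrane.XA + XNa + Xb * zp)


def solve_surface_potential(
    membrane: MembraneSpec,
    solution: SolutionConditions,
    Xb: float = 0.0,
    zp: float = 0.0,
) -> float:
    """Surface potential (V) from equality of the lipid and Grahame charge
    densities at adsorbed fraction Xb with peptide charge zp.

    Both sides are monotone in psi with opposite trends, so the root is
    unique; solved with Brent's method on [-300, +300] mV.
    """
    target = lipid_sigma(membrane, solution, Xb, zp)

    def mismatch(psi: float) -> float:
        return grahame_sigma(psi, solution) - target

    lo, hi = PSI_BRACKET
    if mismatch(lo) * mismatch(hi) > 0:
        raise RuntimeError(
            f"surface-potential root not bracketed in [{lo}, {hi}] V "
            f"(lipid sigma = {target:.4g} C/m^2)"
        )
    return brentq(mismatch, lo, hi, xtol=PSI_XTOL)


def surface_pH(pH_bulk: float, psi: float, temperature: float = 298.15) -> float:
    """pH at the membrane surface from the proton Boltzmann factor.

    pHs = pHb + F*psi / (RT ln 10): a negative surface potential enriches
    protons and lowers the interfacial pH (-47 mV shifts pH by about -0.8).
    """
    return pH_bulk + ph_shift_per_volt(temperature) * psi


def boltzmann_surface_conc(
    Cf: float, zp: float, psi: float, temperature: float = 298.15
) -> float:
    """Near-membrane peptide concentration CM = Cf * exp(-zp e psi / kB T).

    A cationic peptide (zp > 0) at a negative surface potential is enriched
    relative to its bulk (free) concentration Cf.
    """
    if Cf < 0:
        raise ValueError("Cf must be non-negative")
    return Cf * math.exp(-zp * psi / thermal_voltage(temperature))
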