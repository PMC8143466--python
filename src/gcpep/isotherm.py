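"""Self-consistent Gouy-Chapman adsorption isotherms.

The surface potential depends on how much peptide is adsorbed (through the
surface charge density) while the peptide net charge depends on the surface
potential (through charge regulation). At each adsorbed fraction Xb the two
are iterated to a fixed point; a Langmuir-type relation with intrinsic
constant Kint then links Xb to the free peptide concentration via the
Boltzmann-enhanced near-membrane concentration:

    Xb = Kint * Cf * exp(-zp e psi / kB T)

Fluorescence titrations are reduced to experimental (Xb, Cf) points and Kint
is fitted by least squares with the average net charge held fixed, mirroring
the original analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .charge import PeptideIonizationModel, peptide_net_charge, site_fractions
from .constants import thermal_voltage
from .electro import (
    MembraneSpec,
    SolutionConditions,
    solve_surface_potential,
    surface_pH,
)

__all__ = [
    "GCState",
    "BindingPoint",
    "IsothermFit",
    "self_consistent_state",
    "theoretical_isotherm",
    "simulate_titration",
    "fluorescence_to_binding",
    "fit_kint",
    "average_net_charge",
]

PHMode = Literal["bulk", "surface"]

#: damping factor of the zp fixed-point iteration
ZP_DAMPING = 0.5
#: convergence threshold on |delta zp| (elementary charges)
ZP_TOL = 1e-6
ZP_MAX_ITER = 500


@dataclass(frozen=True)
class GCState:
    """Converged electrostatic state at one titration point."""

    Xb: float  # adsorbed peptide per outer-leaflet lipid
    psi: float  # surface potential, V
    zp: float  # peptide net charge, e
    pH_used: float  # pH entering the protonation equation (bulk or surface)
    pHs: float  # surface pH at this state's potential
    site_fractions: dict[str, float]
    Cf: float | None = None  # free peptide, mol/L (set by isotherm callers)
    n_iter: int = 0


@dataclass(frozen=True)
class BindingPoint:
    """One fluorescence-titration point reduced to binding coordinates."""

    L_total: float  # mol/L total lipid
    Fn: float  # fractional fluorescence (fraction bound)
    Xb: float
    Cf: float


@dataclass
class IsothermFit:
    Kint: float  # 1/M
    Kint_sd: float
    zp_mean: float
    zp_sd: float
    residuals: np.ndarray = field(repr=False)
    n_points: int = 0


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed; carries the last iterate."""

    def __init__(self, msg: str, last_state: GCState | None = None):
        super().__init__(msg)
        self.last_state = last_state


def self_consistent_state(
    membrane: MembraneSpec,
    solution: SolutionConditions,
    peptide: PeptideIonizationModel,
    Xb: float,
    pH_mode: PHMode = "surface",
    pHs_policy: Literal["frozen", "track"] = "frozen",
    damping: float = ZP_DAMPING,
    tol: float = ZP_TOL,
    max_iter: int = ZP_MAX_ITER,
) -> GCState:
    """Converge (psi, zp) at a fixed adsorbed fraction Xb.

    Damped fixed-point iteration on zp with an exact inner root-solve for
    psi. In "surface" mode the pH entering the protonation equation is the
    interfacial pH; with the default "frozen" policy it is computed once
    from the unperturbed (Xb = 0) potential, while the potential inside the
    Henderson-Hasselbalch exponent tracks the current Xb. The "track"
    alternative recomputes the interfacial pH from the current potential at
    every iteration.
    """
    if Xb < 0:
        raise ValueError("Xb must be non-negative")
    T = solution.temperature
    psi0 = solve_surface_potential(membrane, solution, 0.0, 0.0)
    if pH_mode == "surface":
        pH_eff = surface_pH(solution.pH_bulk, psi0, T)
    elif pH_mode == "bulk":
        pH_eff = solution.pH_bulk
    else:
        raise ValueError(f"pH_mode must be 'bulk' or 'surface', got {pH_mode!r}")

    zp = 0.0
    psi = psi0
    state = None
    for it in range(1, max_iter + 1):
        psi = solve_surface_potential(membrane, solution, Xb, zp)
        if pH_mode == "surface" and pHs_policy == "track":
            pH_eff = surface_pH(solution.pH_bulk, psi, T)
        zp_new = peptide_net_charge(peptide, pH_eff, psi, T)
        delta = zp_new - zp
        zp = zp + damping * delta
        if abs(delta) < tol:
            fr = site_fractions(peptide, pH_eff, psi, T)
            return GCState(
                Xb=Xb,
                psi=psi,
                zp=zp_new,
                pH_used=pH_eff,
                pHs=surface_pH(solution.pH_bulk, psi, T),
                site_fractions=fr,
                n_iter=it,
            )
    state = GCState(
        Xb=Xb, psi=psi, zp=zp, pH_used=pH_eff,
        pHs=surface_pH(solution.pH_bulk, psi, T),
        site_fractions=site_fractions(peptide, pH_eff, psi, T), n_iter=max_iter,
    )
    raise ConvergenceError(
        f"net charge not converged after {max_iter} iterations", state
    )


def _xb_from_cf(
    membrane: MembraneSpec,
    solution: SolutionConditions,
    peptide: PeptideIonizationModel,
    Kint: float,
    Cf: float,
    pH_mode: PHMode,
    zp_fixed: float | None = None,
) -> GCState:
    """Solve Xb = Kint*Cf*exp(-zp psi / Vt) for Xb at fixed Cf.

    If zp_fixed is given the charge is held there (average-charge fitting
    mode); otherwise zp regulates self-consistently at each Xb.
    """
    T = solution.temperature
    Vt = thermal_voltage(T)

    def state_at(Xb: float) -> GCState:
        if zp_fixed is None:
            return self_consistent_state(membrane, solution, peptide, Xb, pH_mode)
        psi = solve_surface_potential(membrane, solution, Xb, zp_fixed)
        return GCState(
            Xb=Xb, psi=psi, zp=zp_fixed,
            pH_used=solution.pH_bulk,
            pHs=surface_pH(solution.pH_bulk, psi, T),
            site_fractions={},
        )

    def g(Xb: float) -> float:
        st = state_at(Xb)
        return Xb - Kint * Cf * math.exp(-st.zp * st.psi / Vt)

    if Cf == 0.0:
        st = state_at(0.0)
        return GCState(**{**st.__dict__, "Cf": 0.0})
    hi = 1e-3
    while g(hi) < 0 and hi < 1e3:
        hi *= 10.0
    Xb = brentq(g, 0.0, hi, xtol=1e-14, rtol=1e-12)
    st = state_at(Xb)
    return GCState(**{**st.__dict__, "Cf": Cf})


def theoretical_isotherm(
    membrane: MembraneSpec,
    solution: SolutionConditions,
    peptide: PeptideIonizationModel,
    Kint: float,
    Cf_grid: Sequence[float],
    pH_mode: PHMode = "surface",
    zp_fixed: float | None = None,
) -> list[GCState]:
    """Theoretical Xb(Cf) curve: one converged state per free concentration."""
    if Kint <= 0:
        raise ValueError("Kint must be positive")
    return [
        _xb_from_cf(membrane, solution, peptide, Kint, Cf, pH_mode, zp_fixed)
        for Cf in Cf_grid
    ]


def simulate_titration(
    membrane: MembraneSpec,
    solution: SolutionConditions,
    peptide: PeptideIonizationModel,
    Kint: float,
    CP: float,
    L_series: Sequence[float],
    pH_mode: PHMode = "surface",
) -> tuple[list[BindingPoint], list[GCState]]:
    """Forward-model a vesicle-into-peptide titration at total peptide CP.

    At each total lipid L the free and bound peptide satisfy the mass
    balance Cf + Xb*(L/2) = CP together with the adsorption relation; Fn is
    the bound fraction Xb*(L/2)/CP.
    """
    Vt = thermal_voltage(solution.temperature)
    points: list[BindingPoint] = []
    states: list[GCState] = []
    for L in L_series:
        if L <= 0:
            raise ValueError("lipid concentrations must be positive")
        half_L = L / 2.0

        def h(Xb: float) -> float:
            st = self_consistent_state(membrane, solution, peptide, Xb, pH_mode)
            Cf = CP - Xb * half_L
            return Xb - Kint * Cf * math.exp(-st.zp * st.psi / Vt)

        hi = CP / half_L  # Xb at full binding
        Xb = brentq(h, 0.0, hi, xtol=1e-16, rtol=1e-12) if h(hi) > 0 else hi
        Cf = CP - Xb * half_L
        st = self_consistent_state(membrane, solution, peptide, Xb, pH_mode)
        states.append(GCState(**{**st.__dict__, "Cf": Cf}))
        points.append(BindingPoint(L_total=L, Fn=Xb * half_L / CP, Xb=Xb, Cf=Cf))
    return points, states


def fluorescence_to_binding(
    Fn_series: Sequence[float], CP: float, L_series: Sequence[float]
) -> list[BindingPoint]:
    """Reduce fractional fluorescence to (Xb, Cf):
    Xb = Fn*CP/(L/2) (outer leaflet), Cf = CP*(1 - Fn)."""
    if len(Fn_series) != len(L_series):
        raise ValueError("Fn_series and L_series lengths differ")
    out = []
    for Fn, L in zip(Fn_series, L_series):
        if not 0.0 <= Fn <= 1.0:
            raise ValueError(f"Fn = {Fn} outside [0, 1]")
        if L <= 0:
            raise ValueError("lipid concentration must be positive")
        out.append(
            BindingPoint(L_total=L, Fn=Fn, Xb=Fn * CP / (L / 2.0), Cf=CP * (1.0 - Fn))
        )
    return out


def average_net_charge(states: Sequence[GCState]) -> tuple[float, float]:
    """Mean and SD of the net charge over converged states."""
    if not states:
        raise ValueError("no states")
    z = np.array([s.zp for s in states])
    return float(z.mean()), float(z.std(ddof=0))


def fit_kint(
    points: Sequence[BindingPoint],
    membrane: MembraneSpec,
    solution: SolutionConditions,
    peptide: PeptideIonizationModel,
    pH_mode: PHMode = "surface",
    co_fit_zp: bool = False,
) -> IsothermFit:
    """Least-squares Kint from experimental (Xb, Cf) points.

    Default mirrors the original analysis: the net charge is first converged
    at every experimental Xb, its average <zp> is then held fixed and Kint
    alone minimizes the sum of squared Xb residuals. With co_fit_zp the
    average charge is refined together with Kint.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 binding points")
    Cf = np.array([p.Cf for p in points])
    Xb_obs = np.array([p.Xb for p in points])
    if np.allclose(Cf, Cf[0]):
        raise ValueError("degenerate data: all Cf equal")

    states = [
        self_consistent_state(membrane, solution, peptide, p.Xb, pH_mode)
        for p in points
    ]
    zbar, zsd = average_net_charge(states)

    Vt = thermal_voltage(solution.temperature)

    def xb_theo(Kint: float, zp: float) -> np.ndarray:
        return np.array(
            [
                _xb_from_cf(membrane, solution, peptide, Kint, c, pH_mode, zp).Xb
                for c in Cf
            ]
        )

    # initial Kint from the bare-electrostatics estimate at each point
    psi_i = np.array([s.psi for s in states])
    ok = Cf > 0  # fully bound points carry no Kint information for the guess
    k0 = float(np.median(Xb_obs[ok] / (Cf[ok] * np.exp(-zbar * psi_i[ok] / Vt))))
    k0 = max(k0, 1e-6)

    if co_fit_zp:
        def resid(theta):
            return xb_theo(math.exp(theta[0]), theta[1]) - Xb_obs
        sol = least_squares(resid, x0=[math.log(k0), zbar], method="lm")
        Kint = math.exp(sol.x[0])
        zbar = float(sol.x[1])
    else:
        def resid(theta):
            return xb_theo(math.exp(theta[0]), zbar) - Xb_obs
        sol = least_squares(resid, x0=[math.log(k0)], method="lm")
        Kint = math.exp(sol.x[0])

    r = sol.fun
    dof = max(len(points) - sol.x.size, 1)
    s2 = float(r @ r) / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        kint_sd = Kint * math.sqrt(max(cov[0, 0], 0.0))  # delta method on log K
    except np.linalg.LinAlgError:
        kint_sd = float("nan")
    return IsothermFit(
        Kint=Kint, Kint_sd=kint_sd, zp_mean=zbar, zp_sd=zsd,
        residuals=r, n_points=len(points),
    )
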