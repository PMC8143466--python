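"""Synthetic-data generators with known ground truth.

The raw titration series behind the published figures are not deposited, so
every analysis stage is exercised on synthetic data that emulates the
experiments' statistical structure:

- fluorescence titrations: 2 uM peptide titrated with vesicles up to 1.3 mM
  total lipid, forward-modelled through the self-consistent Gouy-Chapman
  adsorption equations, with multiplicative Gaussian noise on intensity
  (default 2%);
- zeta titrations: surface potential from the adsorption model mapped to the
  shear plane (default x = 3.7 A) with additive Gaussian noise (default 2 mV);
- protonation tables: Hill-curve truths sampled binomially, mirroring how
  protonation fractions are estimated from a finite number of simulation
  frames.

Every generator is a pure function of (truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .charge import PEPTIDE_PRESETS, PeptideIonizationModel
from .electro import MembraneSpec, SolutionConditions, debye_kappa
from .isotherm import PHMode, simulate_titration
from .pka import ProtonationTable, hill_model
from .zeta import ZetaPoint, zeta_from_surface

__all__ = [
    "ScenarioTruth",
    "DEFAULT_SCENARIOS",
    "gen_fluorescence_titration",
    "gen_zeta_titration",
    "gen_protonation_table",
]

#: peptide concentration in the fluorescence titrations, mol/L
CP_DEFAULT = 2.0e-6
#: maximum total lipid concentration reached, mol/L
L_MAX_DEFAULT = 1.3e-3
#: shear-plane distance, m
X_SHEAR_DEFAULT = 3.7e-10


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth for one synthetic experimental condition."""

    peptide: str  # preset name
    pH_bulk: float
    Kint: float  # 1/M, intrinsic adsorption constant
    Kp: float  # 1/M, apparent partition constant (fluorescence-only mode)
    pH_mode: PHMode = "surface"
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    CP: float = CP_DEFAULT
    L_max: float = L_MAX_DEFAULT
    noise_fluorescence: float = 0.02  # multiplicative, on intensity
    noise_zeta: float = 0.002  # V, additive

    @property
    def solution(self) -> SolutionConditions:
        return SolutionConditions(pH_bulk=self.pH_bulk)

    @property
    def model(self) -> PeptideIonizationModel:
        return PEPTIDE_PRESETS[self.peptide]


#: the six study conditions (2 peptides x 3 bulk pH). Kint truths are the
#: published surface-pH-mode fits; Kp truths follow the published fold
#: ordering (MP1 weakly pH-sensitive, H-MP1 ~10x weaker at neutral pH).
DEFAULT_SCENARIOS: Mapping[str, ScenarioTruth] = {
    "MP1_pH5.5": ScenarioTruth("MP1", 5.5, Kint=1000.0, Kp=2.0e4),
    "MP1_pH6.5": ScenarioTruth("MP1", 6.5, Kint=1000.0, Kp=1.7e4),
    "MP1_pH7.4": ScenarioTruth("MP1", 7.4, Kint=1000.0, Kp=1.2e4),
    "H-MP1_pH5.5": ScenarioTruth("H-MP1", 5.5, Kint=200.0, Kp=2.5e3),
    "H-MP1_pH6.5": ScenarioTruth("H-MP1", 6.5, Kint=200.0, Kp=1.2e3),
    "H-MP1_pH7.4": ScenarioTruth("H-MP1", 7.4, Kint=200.0, Kp=2.5e2),
}


def gen_fluorescence_titration(
    truth: ScenarioTruth, n_points: int = 12, seed: int = 0
) -> pd.DataFrame:
    """Noisy (pH, CP_M, L_total_M, Fn) series from the adsorption model.

    Lipid additions are log-spaced up to L_max; mass balance
    Cf + Xb*L/2 = CP holds exactly before noise; noise is multiplicative
    Gaussian on the bound-fraction signal, clipped to [0, 1].
    """
    if n_points < 4:
        raise ValueError("need at least 4 titration points")
    rng = np.random.default_rng(seed)
    L = np.logspace(np.log10(truth.L_max / 50.0), np.log10(truth.L_max), n_points)
    points, _ = simulate_titration(
        truth.membrane, truth.solution, truth.model,
        truth.Kint, truth.CP, L, truth.pH_mode,
    )
    Fn = np.array([p.Fn for p in points])
    Fn_noisy = np.clip(Fn * (1.0 + truth.noise_fluorescence * rng.standard_normal(len(Fn))), 0.0, 1.0)
    return pd.DataFrame(
        {"pH": truth.pH_bulk, "CP_M": truth.CP, "L_total_M": L, "Fn": Fn_noisy}
    )


def gen_zeta_titration(
    truth: ScenarioTruth,
    P_over_L_grid: Sequence[float],
    x_shear: float = X_SHEAR_DEFAULT,
    noise_V: float | None = None,
    seed: int = 0,
    L_total: float = 40e-6,
) -> list[ZetaPoint]:
    """Noisy zeta-potential titration at fixed total lipid (default 40 uM).

    For each peptide-to-outer-leaflet-lipid ratio the total peptide is
    CP = ratio * L/2; the adsorption model yields the bound fraction and the
    surface potential, which decays to the shear plane before Gaussian noise
    is added.
    """
    if any(r < 0 for r in P_over_L_grid):
        raise ValueError("P/L ratios must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = truth.noise_zeta if noise_V is None else noise_V
    kappa = debye_kappa(truth.solution)
    T = truth.solution.temperature
    out: list[ZetaPoint] = []
    for ratio in P_over_L_grid:
        if ratio == 0.0:
            from .isotherm import self_consistent_state

            st = self_consistent_state(
                truth.membrane, truth.solution, truth.model, 0.0, truth.pH_mode
            )
        else:
            CP = ratio * L_total / 2.0
            _, states = simulate_titration(
                truth.membrane, truth.solution, truth.model,
                truth.Kint, CP, [L_total], truth.pH_mode,
            )
            st = states[0]
        zeta = zeta_from_surface(st.psi, kappa, x_shear, T)
        if sigma > 0:
            zeta += sigma * rng.standard_normal()
        out.append(ZetaPoint(P_over_L_half=ratio, zeta=zeta))
    return out


def gen_protonation_table(
    truths: Mapping[str, tuple[float, float]],
    pH_list: Sequence[float],
    n_samples: int = 10_000,
    seed: int = 0,
    peptide: str = "synthetic",
    environment: str = "adsorbed",
) -> ProtonationTable:
    """Binomially sampled protonation fractions from Hill-curve truths.

    truths maps residue name -> (pKa, n). Each (residue, pH) cell draws
    Binomial(n_samples, f_true)/n_samples, with the binomial standard error
    sqrt(f(1-f)/n_samples) reported as sd.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for residue, (pka, n) in truths.items():
        for pH in pH_list:
            f_true = float(hill_model(pH, pka, n))
            f_hat = rng.binomial(n_samples, f_true) / n_samples
            sd = float(np.sqrt(f_hat * (1.0 - f_hat) / n_samples))
            rows.append(
                {"residue": residue, "pH": pH, "fraction": f_hat, "sd": sd}
            )
    return ProtonationTable(
        peptide=peptide, environment=environment,  # type: ignore[arg-type]
        data=pd.DataFrame(rows),
    )
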