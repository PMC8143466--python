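"""Hill-equation analysis of per-residue protonation fractions from
constant-pH molecular dynamics (CpHMD).

Each residue's protonated fraction versus pH is fitted with

    f(pH) = 1 / (1 + 10**(n * (pH - pKa)))

giving the apparent pKa and the Hill coefficient n (n > 1: cooperative
proton binding; n < 1: anti-cooperative). pKa shifts between environments
(solution vs membrane-adsorbed) quantify the electrostatic effect of the
bilayer, and the fractions themselves yield a simulation-side net charge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ProtonationTable",
    "HillFit",
    "hill_model",
    "fit_hill",
    "delta_pka",
    "classify_cooperativity",
    "cphmd_net_charge",
    "hill_report",
]


@dataclass(frozen=True)
class ProtonationTable:
    """Per-residue protonated fractions by pH for one peptide/environment.

    data columns: residue, pH, fraction, sd.
    """

    peptide: str
    environment: Literal["solution", "adsorbed"]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"residue", "pH", "fraction", "sd"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"protonation table missing columns: {sorted(missing)}")
        f = self.data["fraction"]
        if ((f < 0) | (f > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")

    def residue(self, name: str) -> pd.DataFrame:
        sub = self.data[self.data["residue"] == name]
        if sub.empty:
            raise KeyError(f"residue {name!r} not in table")
        return sub.sort_values("pH")


@dataclass
class HillFit:
    pKa: float
    n: float
    pKa_sd: float
    n_sd: float
    residuals: np.ndarray = field(repr=False)
    weighted: bool = False


def hill_model(pH, pKa: float, n: float):
    """Protonated fraction: 0.5 at pH = pKa, decreasing in pH with slope
    -n ln(10)/4 at the midpoint."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(n, dtype=float) * (np.asarray(pH, dtype=float) - pKa)))


def _p0(pH: np.ndarray, f: np.ndarray) -> list[float]:
    # pKa guess: linear interpolation of the logit's zero crossing, clipped
    eps = 1e-12
    logit = np.log10(np.clip(f, eps, 1 - eps) / np.clip(1 - f, eps, 1 - eps))
    order = np.argsort(pH)
    pH_s, lg = pH[order], logit[order]
    slope = np.polyfit(pH_s, lg, 1)[0] if len(pH_s) > 1 else -1.0
    n0 = max(-slope, 0.1)
    pka0 = float(pH_s[np.argmin(np.abs(lg))] + lg[np.argmin(np.abs(lg))] / n0)
    return [pka0, n0]


def fit_hill(
    pH: Sequence[float],
    fraction: Sequence[float],
    sd: Sequence[float] | None = None,
) -> HillFit:
    """Weighted nonlinear least squares for (pKa, n).

    Weighting is inverse-variance from the supplied SDs; if SDs are absent,
    or any point reports SD = 0 (fractions pinned at 0/1 to the sampling
    resolution), the fit falls back to unweighted least squares.
    """
    pH = np.asarray(pH, dtype=float)
    f = np.asarray(fraction, dtype=float)
    if pH.size < 2:
        raise ValueError("need at least 2 pH points")
    if np.all(f > 0.99) or np.all(f < 0.01):
        raise ValueError("titration not bracketed: all points saturated")

    sigma = None
    weighted = False
    if sd is not None:
        sd = np.asarray(sd, dtype=float)
        if np.all(sd > 0):
            sigma = sd
            weighted = True

    popt, pcov = curve_fit(
        hill_model, pH, f, p0=_p0(pH, f), sigma=sigma, maxfev=20000
    )
    pKa, n = float(popt[0]), float(popt[1])
    if n <= 0:
        raise RuntimeError("Hill fit converged to non-positive coefficient")
    psd = np.sqrt(np.clip(np.diag(pcov), 0, None))
    resid = f - hill_model(pH, pKa, n)
    return HillFit(
        pKa=pKa, n=n, pKa_sd=float(psd[0]), n_sd=float(psd[1]),
        residuals=resid, weighted=weighted,
    )


def delta_pka(fit_target: HillFit, baseline: "HillFit | float") -> tuple[float, float]:
    """pKa shift (target minus baseline) with SD propagated in quadrature.

    The baseline may be another Hill fit (e.g. the solution-environment fit)
    or a bare reference pKa (SD 0).
    """
    if isinstance(baseline, HillFit):
        return (
            fit_target.pKa - baseline.pKa,
            math.hypot(fit_target.pKa_sd, baseline.pKa_sd),
        )
    return fit_target.pKa - float(baseline), fit_target.pKa_sd


def classify_cooperativity(
    fit: HillFit, tolerance: float = 0.1
) -> Literal["cooperative", "independent", "anti-cooperative"]:
    """n > 1+tol: cooperative; n < 1-tol: anti-cooperative; else independent."""
    if fit.n > 1.0 + tolerance:
        return "cooperative"
    if fit.n < 1.0 - tolerance:
        return "anti-cooperative"
    return "independent"


#: residue-name prefix -> acid/base, for CpHMD tables
_RESIDUE_KIND = {"Asp": "acid", "Glu": "acid", "Lys": "base", "His": "base", "Arg": "base"}


def _kind_of(residue: str) -> str:
    for prefix, kind in _RESIDUE_KIND.items():
        if residue.startswith(prefix):
            return kind
    raise ValueError(f"cannot classify residue {residue!r} as acid or base")


def cphmd_net_charge(
    table: ProtonationTable,
    pH: float,
    nterm_fixed: bool = True,
) -> tuple[float, float]:
    """Peptide net charge from sampled protonation fractions at one pH.

    zp = sum_base f - sum_acid (1 - f), plus +1 for the N-terminus when the
    simulations kept it protonated (the default here, as in the source
    CpHMD runs). SD by quadrature over the per-residue SDs.
    """
    sub = table.data[np.isclose(table.data["pH"], pH)]
    if sub.empty:
        raise ValueError(f"no fractions at pH {pH} in table {table.peptide}")
    zp = 1.0 if nterm_fixed else 0.0
    var = 0.0
    for _, row in sub.iterrows():
        f, s = float(row["fraction"]), float(row["sd"])
        if _kind_of(str(row["residue"])) == "base":
            zp += f
        else:
            zp -= 1.0 - f
        var += s * s
    return zp, math.sqrt(var)


def hill_report(
    tables: dict[str, ProtonationTable],
    reference_pka: dict[str, float],
) -> pd.DataFrame:
    """Fit every titratable (non-saturated) residue of an adsorbed-state table
    and report pKa, Hill n, and the pKa shift.

    `tables` maps environment -> ProtonationTable for one peptide. The shift
    baseline is the solution-environment fit when that titration is
    informative (at least one fraction inside [0.05, 0.95], i.e. the
    midpoint is actually sampled) and the residue's reference pKa otherwise:
    acidic residues are essentially unprotonated in solution across the
    sampled pH range, leaving no constrainable solution curve.
    """
    ads = tables["adsorbed"]
    sol = tables.get("solution")
    rows = []
    for residue in ads.data["residue"].unique():
        sub = ads.residue(residue)
        try:
            fit = fit_hill(sub["pH"], sub["fraction"], sub["sd"])
        except (ValueError, RuntimeError):
            continue  # e.g. lysines pinned at f = 1 across all pH
        baseline: HillFit | float
        baseline_kind = "reference"
        baseline = reference_pka[_res_prefix(residue)]
        if sol is not None:
            try:
                ssub = sol.residue(residue)
                fsol = ssub["fraction"].to_numpy()
                if np.any((fsol >= 0.05) & (fsol <= 0.95)):
                    baseline = fit_hill(ssub["pH"], ssub["fraction"], ssub["sd"])
                    baseline_kind = "solution fit"
            except (KeyError, ValueError, RuntimeError):
                pass
        dpka, dpka_sd = delta_pka(fit, baseline)
        rows.append(
            {
                "peptide": ads.peptide,
                "residue": residue,
                "pKa": fit.pKa,
                "pKa_sd": fit.pKa_sd,
                "hill_n": fit.n,
                "hill_n_sd": fit.n_sd,
                "delta_pKa": dpka,
                "delta_pKa_sd": dpka_sd,
                "baseline": baseline_kind,
                "cooperativity": classify_cooperativity(fit),
            }
        )
    return pd.DataFrame(rows)


def _res_prefix(residue: str) -> str:
    for prefix in _RESIDUE_KIND:
        if residue.startswith(prefix):
            return prefix
    raise ValueError(f"unknown residue {residue!r}")
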