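"""Langmuir-type partition analysis of tryptophan-fluorescence titrations.

Normalized intensity versus outer-leaflet lipid concentration follows

    I([L]) / I0 = 1 + (Imax/I0 - 1) * Kp*g*[L]/2 / (1 + Kp*g*[L]/2)

where Kp is the partition constant (1/M), g the lipid molar volume
(0.75 L/mol) and Imax the intensity at complete binding. The fit works on
intensity ratios only, so it is invariant to a global intensity rescale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["PartitionFit", "partition_model", "fit_partition", "GAMMA_LIPID"]

#: lipid molar volume, dm^3/mol
GAMMA_LIPID = 0.75


@dataclass
class PartitionFit:
    Kp: float  # 1/M
    Kp_sd: float
    Imax_over_I0: float
    Imax_over_I0_sd: float
    residuals: np.ndarray = field(repr=False)
    #: half-width of the ~95% interval on Kp relative to Kp; large values
    #: flag series without curvature that cannot constrain Kp
    Kp_rel_uncertainty: float = float("nan")


def partition_model(
    L_half: float | np.ndarray,
    Kp: float,
    Imax_over_I0: float,
    gamma: float = GAMMA_LIPID,
):
    """Intensity ratio I/I0 at outer-leaflet lipid concentration L_half."""
    s = Kp * gamma * np.asarray(L_half, dtype=float)
    return 1.0 + (Imax_over_I0 - 1.0) * s / (1.0 + s)


def fit_partition(
    L_total: np.ndarray,
    I_ratio: np.ndarray,
    gamma: float = GAMMA_LIPID,
) -> PartitionFit:
    """Nonlinear least squares for (Kp, Imax/I0) on an I/I0 vs L series.

    L_total is the total lipid concentration (mol/L); the model internally
    uses the outer leaflet, L/2. Initial guesses: Imax/I0 from the last
    point, Kp from the lipid concentration at half-maximal signal change.
    """
    L_total = np.asarray(L_total, dtype=float)
    I_ratio = np.asarray(I_ratio, dtype=float)
    if L_total.size < 4:
        raise ValueError("need at least 4 points spanning the saturation curve")
    L_half = L_total / 2.0

    imax0 = max(float(I_ratio[np.argmax(L_half)]), 1.0 + 1e-6)
    half_signal = 1.0 + 0.5 * (imax0 - 1.0)
    idx = int(np.argmin(np.abs(I_ratio - half_signal)))
    Lh = float(L_half[idx]) if L_half[idx] > 0 else float(np.median(L_half[L_half > 0]))
    kp0 = 1.0 / (gamma * Lh)

    try:
        popt, pcov = curve_fit(
            lambda Lh_, Kp, R: partition_model(Lh_, Kp, R, gamma),
            L_half,
            I_ratio,
            p0=[kp0, imax0],
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"partition fit did not converge (p0 Kp={kp0:.3g}, Imax/I0={imax0:.3g})"
        ) from exc
    Kp, R = float(popt[0]), float(popt[1])
    sd = np.sqrt(np.clip(np.diag(pcov), 0, None))
    resid = I_ratio - partition_model(L_half, Kp, R, gamma)
    rel = 2.0 * sd[0] / abs(Kp) if Kp != 0 and math.isfinite(sd[0]) else float("inf")
    return PartitionFit(
        Kp=Kp, Kp_sd=float(sd[0]),
        Imax_over_I0=R, Imax_over_I0_sd=float(sd[1]),
        residuals=resid, Kp_rel_uncertainty=rel,
    )
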