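"""Charge regulation: potential-modified Henderson-Hasselbalch protonation of
titratable sites and the resulting peptide net charge.

A site at the membrane surface feels the local electrostatic potential, which
shifts its effective pH. For a site with reference pKa the protonated
fraction is

    f = 1 / (1 + 10**(pH + F*psi/(RT ln10) - pKa))

(negative psi raises f). Acidic sites contribute -count*(1 - f) to the net
charge, basic sites +count*f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

from .constants import ph_shift_per_volt

__all__ = [
    "IonizableSite",
    "PeptideIonizationModel",
    "PEPTIDE_PRESETS",
    "protonation_fraction",
    "site_fractions",
    "peptide_net_charge",
    "potential_from_fraction",
    "REFERENCE_PKA",
]

#: reference (aqueous, unperturbed) pKa values used throughout
REFERENCE_PKA: Mapping[str, float] = {
    "Asp": 4.0,
    "Lys": 10.4,
    "His": 6.5,
    "Nterm": 8.0,
}


@dataclass(frozen=True)
class IonizableSite:
    name: str
    kind: Literal["acid", "base"]
    count: int
    pKa_ref: float

    def __post_init__(self) -> None:
        if self.kind not in ("acid", "base"):
            raise ValueError(f"kind must be 'acid' or 'base', got {self.kind!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not 0.0 < self.pKa_ref < 14.0:
            raise ValueError("pKa_ref must be in (0, 14)")


@dataclass(frozen=True)
class PeptideIonizationModel:
    """Titratable-site composition of one peptide.

    Both study peptides are 14-mers with an amidated (non-titratable)
    C-terminus: MP1 has 2 Asp + 3 Lys + the N-terminus, H-MP1 replaces the
    lysines with histidines.
    """

    name: str
    sites: tuple[IonizableSite, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("peptide model needs at least one ionizable site")

    @property
    def n_acid(self) -> int:
        return sum(s.count for s in self.sites if s.kind == "acid")

    @property
    def n_base(self) -> int:
        return sum(s.count for s in self.sites if s.kind == "base")


def _mk(name: str, sites: list[tuple[str, str, int, float]]) -> PeptideIonizationModel:
    return PeptideIonizationModel(
        name, tuple(IonizableSite(n, k, c, p) for n, k, c, p in sites)
    )


PEPTIDE_PRESETS: Mapping[str, PeptideIonizationModel] = {
    "MP1": _mk(
        "MP1",
        [
            ("Asp", "acid", 2, REFERENCE_PKA["Asp"]),
            ("Lys", "base", 3, REFERENCE_PKA["Lys"]),
            ("Nterm", "base", 1, REFERENCE_PKA["Nterm"]),
        ],
    ),
    "H-MP1": _mk(
        "H-MP1",
        [
            ("Asp", "acid", 2, REFERENCE_PKA["Asp"]),
            ("His", "base", 3, REFERENCE_PKA["His"]),
            ("Nterm", "base", 1, REFERENCE_PKA["Nterm"]),
        ],
    ),
}


def protonation_fraction(
    pH: float, psi: float, pKa: float, temperature: float = 298.15
) -> float:
    """Protonated fraction of a site at local potential psi (V)."""
    expo = pH + ph_shift_per_volt(temperature) * psi - pKa
    return 1.0 / (1.0 + 10.0**expo)


def site_fractions(
    model: PeptideIonizationModel,
    pH: float,
    psi: float,
    temperature: float = 298.15,
    fixed_fractions: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Protonated fraction per site; entries in fixed_fractions are pinned
    (e.g. Nterm -> 1.0 to mirror simulations that keep it protonated)."""
    fixed = fixed_fractions or {}
    out: dict[str, float] = {}
    for s in model.sites:
        if s.name in fixed:
            out[s.name] = float(fixed[s.name])
        else:
            out[s.name] = protonation_fraction(pH, psi, s.pKa_ref, temperature)
    return out


def peptide_net_charge(
    model: PeptideIonizationModel,
    pH: float,
    psi: float,
    temperature: float = 298.15,
    fixed_fractions: Mapping[str, float] | None = None,
) -> float:
    """Net charge zp = sum_base count*f - sum_acid count*(1-f).

    Bounded by [-n_acid, +n_base] and monotonically decreasing in pH.
    """
    fr = site_fractions(model, pH, psi, temperature, fixed_fractions)
    zp = 0.0
    for s in model.sites:
        f = fr[s.name]
        zp += s.count * f if s.kind == "base" else -s.count * (1.0 - f)
    return zp


def potential_from_fraction(
    f: float, pH: float, pKa: float, temperature: float = 298.15
) -> float:
    """Invert the potential-modified Henderson-Hasselbalch relation.

    Returns the local potential (V) at which a site with the given reference
    pKa shows protonated fraction f at the given pH. Exact closed-form
    inverse of :func:`protonation_fraction`.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must be strictly inside (0, 1): potential unbounded")
    return (pKa - pH + math.log10(1.0 / f - 1.0)) / ph_shift_per_volt(temperature)
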