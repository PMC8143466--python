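"""Bundled datasets: published per-residue CpHMD protonation fractions for
MP1 and H-MP1 in solution and adsorbed on the 7POPC:3POPG bilayer, at pH
5.5, 6.5 and 7.4 (150 mM NaCl, 298 K), with sampling standard errors."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .pka import ProtonationTable

__all__ = ["load_cphmd_fractions", "cphmd_table"]


def load_cphmd_fractions() -> pd.DataFrame:
    """Full bundled table: peptide, environment, residue, pH, fraction, sd."""
    ref = resources.files("gcpep.data").joinpath("cphmd_protonation.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def cphmd_table(peptide: str, environment: str) -> ProtonationTable:
    """One peptide/environment slice as a :class:`ProtonationTable`."""
    df = load_cphmd_fractions()
    sub = df[(df["peptide"] == peptide) & (df["environment"] == environment)]
    if sub.empty:
        raise KeyError(f"no bundled fractions for {peptide!r}/{environment!r}")
    return ProtonationTable(
        peptide=peptide,
        environment=environment,  # type: ignore[arg-type]
        data=sub[["residue", "pH", "fraction", "sd"]].reset_index(drop=True),
    )
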