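"""CSV/JSON/YAML readers and writers for the analysis pipeline.

All CSV parsing is column-name based (order-insensitive), UTF-8, dot decimal
separator. Schemas:

- fluorescence titration: pH, CP_M, L_total_M, Fn
- zeta titration: P_over_L_half, zeta_mV [, DH_nm, pH]
- protonation fractions: peptide, environment, residue, pH, fraction, sd
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .isotherm import GCState
from .pka import ProtonationTable
from .zeta import ZetaPoint

__all__ = [
    "read_fluorescence_csv",
    "read_zeta_csv",
    "write_zeta_csv",
    "read_protonation_csv",
    "write_states_csv",
    "load_config",
]


def _require_columns(df: pd.DataFrame, cols: set[str], path: Path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def _check_exists(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


def read_fluorescence_csv(path: str | Path) -> pd.DataFrame:
    p = _check_exists(path)
    df = pd.read_csv(p)
    _require_columns(df, {"pH", "CP_M", "L_total_M", "Fn"}, p)
    return df


def read_zeta_csv(path: str | Path) -> list[ZetaPoint]:
    p = _check_exists(path)
    df = pd.read_csv(p)
    _require_columns(df, {"P_over_L_half", "zeta_mV"}, p)
    return [
        ZetaPoint(
            P_over_L_half=float(r["P_over_L_half"]),
            zeta=float(r["zeta_mV"]) * 1e-3,
            DH=float(r["DH_nm"]) * 1e-9 if "DH_nm" in df.columns else None,
        )
        for _, r in df.iterrows()
    ]


def write_zeta_csv(points: Sequence[ZetaPoint], path: str | Path) -> None:
    pd.DataFrame(
        {
            "P_over_L_half": [p.P_over_L_half for p in points],
            "zeta_mV": [p.zeta * 1e3 for p in points],
        }
    ).to_csv(path, index=False)


def read_protonation_csv(path: str | Path) -> pd.DataFrame:
    p = _check_exists(path)
    df = pd.read_csv(p)
    _require_columns(df, {"peptide", "environment", "residue", "pH", "fraction", "sd"}, p)
    return df


def protonation_tables(df: pd.DataFrame) -> dict[tuple[str, str], ProtonationTable]:
    """Split a long-format fraction table into per-(peptide, environment)
    :class:`ProtonationTable` objects."""
    out = {}
    for (pep, env), sub in df.groupby(["peptide", "environment"]):
        out[(pep, env)] = ProtonationTable(
            peptide=pep, environment=env,  # type: ignore[arg-type]
            data=sub[["residue", "pH", "fraction", "sd"]].reset_index(drop=True),
        )
    return out


def write_states_csv(states: Sequence[GCState], path: str | Path) -> None:
    rows = []
    for s in states:
        row: dict[str, Any] = {
            "Xb": s.Xb,
            "Cf_M": s.Cf,
            "psi_mV": s.psi * 1e3,
            "zp": s.zp,
            "pHs": s.pHs,
        }
        for name, f in s.site_fractions.items():
            row[f"f_{name}"] = f
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON run configuration."""
    p = _check_exists(path)
    text = p.read_text(encoding="utf-8")
    if p.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)
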