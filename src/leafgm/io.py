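"""Ingestion and serialisation of gas-exchange datasets.

Reads instrument-style CSV exports (LI-6400 column dialect by default) into
validated tidy tables, converting leaf temperature from Celsius to Kelvin
on ingest.  Rows failing physical validation are collected into a rejects
report with their source line numbers — never silently dropped.  All
written artifacts are plain CSV with a ``#``-prefixed header comment block
(tool version, seed, config hash) for auditability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd

from .config import KELVIN_OFFSET

#: Default column mapping from LI-6400 export names to package names.
LI6400_COLUMN_MAP = {
    "Photo": "An",
    "Cond": "gs",
    "Ci": "Ci",
    "Tleaf": "Tleaf",
    "PARi": "PPFD",
    "Fs": "Fs",
    "Fm'": "Fm_prime",
    "CO2S": "Ca",
    "RH_S": "RH",
}

REQUIRED_COLUMNS = ("An", "gs", "Ci", "Tleaf", "PPFD", "Fs", "Fm_prime")
KEY_COLUMNS = ("plant_id", "day", "treatment")


@dataclass
class Dataset:
    """The joined tables of one experiment run.

    ``observations`` is required; water status, A/Ci curves and the truth
    table (synthetic runs only) are optional.  Tables join on
    (plant_id, day, treatment).
    """

    observations: pd.DataFrame
    water_status: Optional[pd.DataFrame] = None
    aci: Optional[pd.DataFrame] = None
    truth: Optional[pd.DataFrame] = None
    metadata: dict[str, Any] = field(default_factory=dict)


def _validate_row(row: Mapping[str, float]) -> Optional[str]:
    if row["gs"] <= 0:
        return f"gs must be positive (got {row['gs']})"
    if row["Ci"] < 0:
        return f"Ci must be non-negative (got {row['Ci']})"
    if row["Tleaf"] <= 0:
        return f"Tleaf must be positive Kelvin (got {row['Tleaf']})"
    if row["PPFD"] < 0:
        return f"PPFD must be non-negative (got {row['PPFD']})"
    if row["Fm_prime"] <= 0:
        return f"Fm' must be positive (got {row['Fm_prime']})"
    if row["Fs"] < 0 or row["Fs"] > row["Fm_prime"]:
        return f"need 0 <= Fs <= Fm' (got Fs={row['Fs']}, Fm'={row['Fm_prime']})"
    return None


def read_gas_exchange_table(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    temperature_unit: str = "C",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a gas-exchange CSV.

    Parameters
    ----------
    path
        CSV file; ``#``-prefixed comment lines are skipped.
    column_map
        Mapping from file column names to package names; defaults to the
        LI-6400 export dialect.  Columns already carrying package names are
        accepted as-is.
    temperature_unit
        "C" (default; converted to Kelvin on ingest) or "K".

    Returns ``(accepted, rejects)``; rejects carries the 1-based source
    line number and the failure reason per row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, comment="#", skip_blank_lines=True)
    cmap = dict(LI6400_COLUMN_MAP if column_map is None else column_map)
    renamed = raw.rename(columns={k: v for k, v in cmap.items() if k in raw.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in renamed.columns]
    if missing:
        inverse = {v: k for k, v in cmap.items()}
        names = ", ".join(inverse.get(c, c) for c in missing)
        raise ValueError(f"missing column {names}")
    if temperature_unit not in ("C", "K"):
        raise ValueError(f"temperature_unit must be 'C' or 'K', got {temperature_unit!r}")
    if temperature_unit == "C":
        renamed["Tleaf"] = renamed["Tleaf"] + KELVIN_OFFSET

    accepted_rows, reject_rows = [], []
    for pos, (_, row) in enumerate(renamed.iterrows()):
        try:
            numeric = {c: float(row[c]) for c in REQUIRED_COLUMNS}
        except (TypeError, ValueError):
            reject_rows.append({"line": pos + 2, "reason": "unparseable row"})
            continue
        if any(pd.isna(v) for v in numeric.values()):
            reject_rows.append({"line": pos + 2, "reason": "unparseable row"})
            continue
        reason = _validate_row(numeric)
        if reason is not None:
            reject_rows.append({"line": pos + 2, "reason": reason})
        else:
            clean = row.copy()
            for c, v in numeric.items():
                clean[c] = v
            accepted_rows.append(clean)
    accepted = pd.DataFrame(accepted_rows).reset_index(drop=True)
    rejects = pd.DataFrame(reject_rows, columns=["line", "reason"])
    return accepted, rejects


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path,
                metadata: Optional[Mapping[str, Any]] = None) -> None:
    """Write a CSV with a ``#`` header comment block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# leafgm 0.1.0\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (or any plain CSV)."""
    return pd.read_csv(path, comment="#")
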