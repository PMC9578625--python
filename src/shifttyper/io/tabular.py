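"""Plain tabular spin-system files and TSV/CSV report writing.

The tabular spin-system format is a delimited text file with a header row.
Recognized columns: ``id``, ``type`` (or ``residue_type``), ``position``
(or ``sequence_position``), ``source``, and any of the seven shift names.
Empty cells mean missing.  The delimiter is chosen by extension: ``.csv``
uses a comma, anything else a tab.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from ..types import CANONICAL_SHIFTS, SpinSystem

_ALIASES = {
    "id": "id",
    "type": "residue_type",
    "residue_type": "residue_type",
    "position": "sequence_position",
    "sequence_position": "sequence_position",
    "source": "source",
}
_ACCEPTED = sorted(set(_ALIASES) | set(CANONICAL_SHIFTS))


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def parse_tabular_spin_systems(path) -> list[SpinSystem]:
    """Read spin systems from a delimited text file.

    Raises ``ValueError`` for column names outside the accepted set.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str, keep_default_na=False)
    columns = {}
    for col in df.columns:
        key = col.strip()
        if key in CANONICAL_SHIFTS:
            columns[col] = key
        elif key.lower() in _ALIASES:
            columns[col] = _ALIASES[key.lower()]
        else:
            raise ValueError(
                f"unknown column {col!r}; accepted names: {_ACCEPTED}"
            )
    if "id" not in columns.values():
        raise ValueError("missing required column 'id'")
    out = []
    for i, row in df.iterrows():
        fields = {"shifts": {}}
        for col, key in columns.items():
            cell = str(row[col]).strip()
            if cell == "":
                continue
            if key in CANONICAL_SHIFTS:
                value = float(cell)
                if not math.isfinite(value):
                    raise ValueError(f"row {i + 2}: non-finite {key} value")
                fields["shifts"][key] = value
            elif key == "sequence_position":
                fields[key] = int(cell)
            else:
                fields[key] = cell
        out.append(SpinSystem(**fields))
    return out


def write_spin_systems(path, spin_systems: list[SpinSystem]) -> None:
    """Write spin systems in the tabular format (round-trips with the parser)."""
    path = Path(path)
    rows = []
    for ss in spin_systems:
        row = {
            "id": ss.id,
            "type": ss.residue_type or "",
            "position": "" if ss.sequence_position is None else ss.sequence_position,
            "source": ss.source or "",
        }
        for name in CANONICAL_SHIFTS:
            row[name] = repr(ss.shifts[name]) if name in ss.shifts else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_delimiter(path), index=False)


def write_report(path, rows: list[dict], columns: list[str] | None = None) -> None:
    """Write a list of flat dicts as a TSV/CSV report."""
    path = Path(path)
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep=_delimiter(path), index=False)


def parse_chains_table(path) -> list[dict]:
    """Read a chains table: columns ``chain_id``, ``members``, optional ``pre``.

    ``members`` is a semicolon- or space-separated list of spin-system ids,
    ordered N-to-C.  Returns dicts with keys chain_id / member_ids / pre_id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str, keep_default_na=False)
    need = {"chain_id", "members"}
    if not need.issubset(df.columns):
        raise ValueError(f"chains table needs columns {sorted(need)}")
    out = []
    for _, row in df.iterrows():
        members = [m for m in row["members"].replace(";", " ").split() if m]
        if not members:
            raise ValueError(f"chain {row['chain_id']!r} has no members")
        pre = str(row["pre"]).strip() if "pre" in df.columns else ""
        out.append(
            {
                "chain_id": row["chain_id"],
                "member_ids": members,
                "pre_id": pre or None,
            }
        )
    return out
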