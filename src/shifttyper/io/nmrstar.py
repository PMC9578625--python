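"""Reading assigned chemical shifts from NMR-STAR v2 / v3 entries.

Only the assigned-chemical-shift loop is consumed; the rest of the entry is
tokenized and skipped.  Atom names are normalized to the seven canonical
shift names through a versioned mapping table shipped as package data;
stereo pairs (HB2/HB3, and HA2/HA3 for glycine) collapse to a single value
by arithmetic mean.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from importlib import resources
from pathlib import Path

from ..types import SpinSystem, one_letter

logger = logging.getLogger(__name__)


class NmrStarFormatError(ValueError):
    """The file does not contain a usable assigned-chemical-shift loop."""


def _load_atom_name_map() -> tuple[dict[str, str], dict[str, str]]:
    text = resources.files("shifttyper.data").joinpath("atom_name_map.json").read_text()
    doc = json.loads(text)
    return doc["direct"], doc["stereo_average"]


_DIRECT, _STEREO = _load_atom_name_map()

# Tag names identifying the shift loop columns in the two dialects.
_V3_TAGS = {
    "seq": "_Atom_chem_shift.Seq_ID",
    "comp": "_Atom_chem_shift.Comp_ID",
    "atom": "_Atom_chem_shift.Atom_ID",
    "value": "_Atom_chem_shift.Val",
}
_V2_TAGS = {
    "seq": "_Residue_seq_code",
    "comp": "_Residue_label",
    "atom": "_Atom_name",
    "value": "_Chem_shift_value",
}


def _tokenize(text: str):
    """Yield STAR tokens: bare values, quoted values, semicolon blocks."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            # multi-line value: consume until the closing semicolon
            i += 1
            block = []
            while i < len(lines) and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            yield "\n".join(block)
            i += 1
            continue
        pos = 0
        n = len(line)
        while pos < n:
            ch = line[pos]
            if ch in " \t":
                pos += 1
                continue
            if ch == "#":
                break
            if ch in "'\"":
                end = line.find(ch, pos + 1)
                # quotes close only when followed by whitespace/EOL
                while end != -1 and end + 1 < n and line[end + 1] not in " \t":
                    end = line.find(ch, end + 1)
                if end == -1:
                    yield line[pos + 1:]
                    pos = n
                else:
                    yield line[pos + 1:end]
                    pos = end + 1
            else:
                end = pos
                while end < n and line[end] not in " \t":
                    end += 1
                yield line[pos:end]
                pos = end
        i += 1


def _iter_loops(text: str):
    """Yield (tags, rows) for every loop in the entry."""
    tokens = iter(_tokenize(text))
    for tok in tokens:
        if tok.lower() != "loop_":
            continue
        tags: list[str] = []
        values: list[str] = []
        in_header = True
        for tok2 in tokens:
            low = tok2.lower()
            if in_header and tok2.startswith("_"):
                tags.append(tok2)
                continue
            in_header = False
            if low == "stop_":
                break
            if low == "loop_" or tok2.startswith(("save_", "data_")):
                break  # malformed / unterminated loop; salvage what we have
            values.append(tok2)
        if not tags:
            continue
        ncol = len(tags)
        rows = [values[i:i + ncol] for i in range(0, len(values) - ncol + 1, ncol)]
        yield tags, rows


def _find_shift_loop(text: str):
    for tags, rows in _iter_loops(text):
        lower = [t.lower() for t in tags]
        for spec in (_V3_TAGS, _V2_TAGS):
            want = {k: spec[k].lower() for k in spec}
            if all(any(t == w for t in lower) for w in want.values()):
                idx = {k: lower.index(w) for k, w in want.items()}
                return idx, rows
    return None


def parse_nmrstar_shifts(path, entry_id: str | None = None) -> list[SpinSystem]:
    """Parse one NMR-STAR entry into per-residue spin systems.

    Each residue with at least one recognized shift yields a
    :class:`SpinSystem` with ``residue_type`` and ``sequence_position``
    filled from the loop.  Shifts whose atom names fall outside the
    normalization table, and residues with non-standard residue codes, are
    skipped with a logged warning.  Ambiguity codes are ignored.
    """
    path = Path(path)
    if entry_id is None:
        entry_id = path.stem
    text = path.read_text()
    found = _find_shift_loop(text)
    if found is None:
        raise NmrStarFormatError(
            f"entry {entry_id!r}: no assigned-chemical-shift loop found"
        )
    idx, rows = found
    # residue -> canonical name -> list of values (stereo pairs collect 2)
    per_residue: dict[tuple[int, str], dict[str, list[float]]] = defaultdict(
        lambda: defaultdict(list)
    )
    raw_atoms: dict[tuple[int, str], dict[str, float]] = defaultdict(dict)
    skipped_codes: set[str] = set()
    for row in rows:
        try:
            seq = int(row[idx["seq"]])
            raw_value = row[idx["value"]]
            atom = row[idx["atom"]].upper()
            comp = row[idx["comp"]]
        except (ValueError, IndexError):
            continue
        if raw_value in (".", "?"):
            continue
        try:
            value = float(raw_value)
        except ValueError:
            continue
        try:
            res = one_letter(comp)
        except ValueError:
            skipped_codes.add(comp)
            continue
        canonical = _DIRECT.get(atom) or _STEREO.get(atom)
        if canonical is None:
            continue
        per_residue[(seq, res)][canonical].append(value)
        if atom in _STEREO:
            raw_atoms[(seq, res)][atom] = value
    if skipped_codes:
        logger.warning(
            "entry %s: skipped residues with unknown codes %s",
            entry_id, sorted(skipped_codes),
        )
    spin_systems = []
    for (seq, res), shift_lists in sorted(per_residue.items()):
        shifts = {
            name: float(sum(vals) / len(vals)) for name, vals in shift_lists.items()
        }
        ss = SpinSystem(
            id=f"{entry_id}:{seq}",
            shifts=shifts,
            residue_type=res,
            source=entry_id,
            sequence_position=seq,
            raw_shifts=raw_atoms.get((seq, res)) or None,
        )
        if ss.violates_structure():
            logger.warning(
                "entry %s residue %d (%s): structurally impossible shifts present",
                entry_id, seq, res,
            )
        spin_systems.append(ss)
    return spin_systems
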