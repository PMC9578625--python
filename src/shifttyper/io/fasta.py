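"""FASTA reading via Biopython."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from ..types import ProteinSequence


def parse_fasta(path, record_id: str | None = None) -> ProteinSequence:
    """Read one protein sequence from a FASTA file.

    The first record is used unless ``record_id`` names another one.
    Lowercase letters are normalized to uppercase; letters outside the
    20-residue alphabet are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if record_id is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"{path}: no record with id {record_id!r}")
        rec = matches[0]
    return ProteinSequence(rec.id, str(rec.seq).upper())


def write_fasta(path, sequence: ProteinSequence, width: int = 60) -> None:
    lines = [f">{sequence.id}"]
    for i in range(0, len(sequence.residues), width):
        lines.append(sequence.residues[i:i + width])
    Path(path).write_text("\n".join(lines) + "\n")
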