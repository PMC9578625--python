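"""Sparky .list peak-list reading and writing.

The dialect is one peak per line: an assignment column followed by w1 and
w2 in ppm.  For 15N-HSQC lists w1 is the nitrogen axis and w2 the proton
axis.  A label of ``?`` (or any run of ``?-?`` placeholders) means
unassigned.
"""

from __future__ import annotations

from pathlib import Path

from ..types import Peak2D


def parse_sparky_list(path) -> list[Peak2D]:
    """Parse a Sparky .list file into peaks.

    Returns peaks with ``n_ppm`` taken from w1 and ``h_ppm`` from w2.
    Raises ``ValueError`` with the line number for non-numeric coordinates.
    """
    path = Path(path)
    peaks = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.split()
        if fields[0].lower() == "assignment":  # header line
            continue
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected label w1 w2")
        label = fields[0]
        try:
            w1 = float(fields[1])
            w2 = float(fields[2])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-numeric peak coordinate"
            ) from None
        if label.replace("?", "").replace("-", "") == "":
            label = None
        peaks.append(Peak2D(label=label, n_ppm=w1, h_ppm=w2))
    return peaks


def write_sparky_list(path, peaks: list[Peak2D]) -> None:
    lines = [f"{'Assignment':>17s} {'w1':>8s} {'w2':>8s}", ""]
    for p in peaks:
        label = p.label if p.label else "?-?"
        lines.append(f"{label:>17s} {p.n_ppm:8.3f} {p.h_ppm:8.3f}")
    Path(path).write_text("\n".join(lines) + "\n")
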