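"""Core domain types shared by every module.

A *spin system* is the set of chemical shifts (in ppm) observed for one
residue, gathered across spectra.  Shift names are restricted to the seven
canonical backbone/side-chain nuclei used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Canonical shift names, in training-table column order.
CANONICAL_SHIFTS: tuple[str, ...] = ("HN", "N", "CO", "CA", "CB", "HA", "HB")

#: The 20 standard residue types, alphabetical by one-letter code.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Shifts that a residue type cannot have for structural reasons:
#: glycine has no beta nuclei, proline has no amide proton.
NATURALLY_ABSENT: dict[str, frozenset[str]] = {
    "G": frozenset({"CB", "HB"}),
    "P": frozenset({"HN"}),
}


def one_letter(code: str) -> str:
    """Normalize a residue code (1- or 3-letter) to upper-case one-letter.

    Raises ``ValueError`` for codes outside the 20 standard types.
    """
    code = code.strip().upper()
    if len(code) == 3:
        try:
            return THREE_TO_ONE[code]
        except KeyError:
            raise ValueError(f"unknown residue code: {code!r}") from None
    if len(code) == 1 and code in AMINO_ACIDS:
        return code
    raise ValueError(f"unknown residue code: {code!r}")


@dataclass
class SpinSystem:
    """One residue's named chemical shifts, possibly incomplete.

    Parameters
    ----------
    id:
        Text identifier (unique within a protein).
    shifts:
        Mapping from canonical shift name to value in ppm.  Missing shifts
        are simply absent — never encoded as sentinel numbers.
    residue_type:
        Optional one-letter amino-acid code (the true type, when known).
    source:
        Optional protein or database-entry identifier.
    sequence_position:
        Optional 1-based position in the protein sequence.
    raw_shifts:
        Optional pre-normalization record (e.g. separate HB2/HB3 values)
        kept for structural-exclusion rules.
    """

    id: str
    shifts: dict[str, float] = field(default_factory=dict)
    residue_type: str | None = None
    source: str | None = None
    sequence_position: int | None = None
    raw_shifts: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name, value in self.shifts.items():
            if name not in CANONICAL_SHIFTS:
                raise ValueError(
                    f"spin system {self.id!r}: unknown shift name {name!r}; "
                    f"expected one of {CANONICAL_SHIFTS}"
                )
            if not math.isfinite(value):
                raise ValueError(
                    f"spin system {self.id!r}: non-finite value for {name}"
                )
        if self.residue_type is not None:
            self.residue_type = one_letter(self.residue_type)

    def present(self, shift_names) -> tuple[str, ...]:
        """Shift names from ``shift_names`` that this spin system carries."""
        return tuple(s for s in shift_names if s in self.shifts)

    def is_complete_for(self, shift_names, respect_natural_absence: bool = True) -> bool:
        """True when all shifts in ``shift_names`` are present.

        When ``respect_natural_absence`` is set and the residue type is
        known, shifts the type cannot have (Gly CB/HB, Pro HN) are not
        required.
        """
        required = set(shift_names)
        if respect_natural_absence and self.residue_type in NATURALLY_ABSENT:
            required -= NATURALLY_ABSENT[self.residue_type]
        return required.issubset(self.shifts)

    def violates_structure(self) -> bool:
        """True if shifts incompatible with the stated residue type exist."""
        if self.residue_type in NATURALLY_ABSENT:
            return bool(NATURALLY_ABSENT[self.residue_type] & self.shifts.keys())
        return False


@dataclass(frozen=True)
class ShiftSubset:
    """A named, ordered selection of shift columns.

    The three standard subsets mirror typical experimental setups:
    (i) amide-walk shifts, (ii) the four side-chain-adjacent shifts from a
    single 4D experiment, (iii) all seven.
    """

    name: str
    shift_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.shift_names)) != len(self.shift_names):
            raise ValueError("duplicate shift names in subset")
        unknown = set(self.shift_names) - set(CANONICAL_SHIFTS)
        if unknown:
            raise ValueError(f"unknown shift names: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.shift_names)


SUBSET_I = ShiftSubset("i", ("HN", "N", "CA", "CO"))
SUBSET_II = ShiftSubset("ii", ("CA", "CB", "HA", "HB"))
SUBSET_III = ShiftSubset("iii", CANONICAL_SHIFTS)

SUBSETS: dict[str, ShiftSubset] = {"i": SUBSET_I, "ii": SUBSET_II, "iii": SUBSET_III}


def get_subset(name: str) -> ShiftSubset:
    try:
        return SUBSETS[name]
    except KeyError:
        raise ValueError(
            f"unknown subset {name!r}; valid subsets: {sorted(SUBSETS)}"
        ) from None


@dataclass
class ProteinSequence:
    """An amino-acid sequence with an identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residue letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass
class Peak2D:
    """A 2D (H, N) peak with an optional assignment label."""

    label: str | None
    h_ppm: float
    n_ppm: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h_ppm) and math.isfinite(self.n_ppm)):
            raise ValueError("peak coordinates must be finite")


@dataclass
class Chain:
    """An ordered run of sequentially linked spin systems.

    ``members[0]`` is the most N-terminal member.  ``pre`` optionally holds
    the (usually incomplete) spin system of the residue preceding the chain.
    """

    id: str
    members: list[SpinSystem]
    pre: SpinSystem | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"chain {self.id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)
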