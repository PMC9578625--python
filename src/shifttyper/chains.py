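"""Mapping spin-system chains onto a protein sequence.

For every chain position the classifier yields residue-type posteriors;
candidate sequences arise from the Cartesian product of the probable types
per position, and candidates whose sequence never occurs in the protein are
flagged as discarded.  The chain direction is N-to-C, with the optional
"pre" residue prepended.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from . import lda
from .types import Chain, ProteinSequence, ShiftSubset, SpinSystem

logger = logging.getLogger(__name__)

DEFAULT_INCLUSION_THRESHOLD = 0.01
DEFAULT_TOP_TYPES = 5
DEFAULT_MAX_CANDIDATES = 10_000

#: CB windows (ppm) for the residue types recognizable by eye in
#: disordered-protein spectra.  Fixture-grade heuristics for the manual
#: baseline only — not classifier input.
_MANUAL_CB_WINDOWS = {"A": (15.0, 22.0), "S": (62.0, 65.5), "T": (68.0, 72.5)}


@dataclass
class ChainCandidate:
    sequence: str
    joint_probability: float
    positions: list[int] = field(default_factory=list)
    """1-based start offsets of exact occurrences in the protein sequence."""

    @property
    def discarded(self) -> bool:
        return not self.positions


def position_posteriors(
    chain: Chain,
    training: list[SpinSystem],
    subset: ShiftSubset,
    allowed_types: set[str] | None = None,
) -> list[dict[str, float]]:
    """Per-position residue-type posteriors, pre first if present."""
    members = ([chain.pre] if chain.pre is not None else []) + list(chain.members)
    results = lda.classify_batch(members, training, subset, allowed_types)
    return [r.probabilities for r in results]


def enumerate_candidates(
    chain: Chain,
    training: list[SpinSystem],
    subset: ShiftSubset,
    allowed_types: set[str] | None = None,
    inclusion_threshold: float = DEFAULT_INCLUSION_THRESHOLD,
    top_types: int = DEFAULT_TOP_TYPES,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
    posteriors: list[dict[str, float]] | None = None,
) -> list[ChainCandidate]:
    """All probable amino-acid sequences for a chain.

    Per position, types with posterior >= ``inclusion_threshold`` are
    retained (capped at the ``top_types`` most probable; falling back to the
    single best type if none pass).  Candidates are the Cartesian product,
    sorted by decreasing joint probability (product over positions) and
    truncated at ``max_candidates`` with a warning.
    """
    if posteriors is None:
        posteriors = position_posteriors(chain, training, subset, allowed_types)
    per_position: list[list[tuple[str, float]]] = []
    for i, probs in enumerate(posteriors):
        ranked = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
        kept = [(t, p) for t, p in ranked[:top_types] if p >= inclusion_threshold]
        if not kept:
            logger.warning(
                "chain %s position %d: no type above threshold %.3g; "
                "falling back to best type %s",
                chain.id, i, inclusion_threshold, ranked[0][0],
            )
            kept = [ranked[0]]
        per_position.append(kept)
    candidates = []
    truncated = False
    for combo in itertools.product(*per_position):
        if len(candidates) >= max_candidates:
            truncated = True
            break
        seq = "".join(t for t, _ in combo)
        prob = 1.0
        for _, p in combo:
            prob *= p
        candidates.append(ChainCandidate(seq, prob))
    if truncated:
        logger.warning(
            "chain %s: candidate cap %d reached; list truncated", chain.id, max_candidates
        )
    candidates.sort(key=lambda c: (-c.joint_probability, c.sequence))
    return candidates


def filter_by_sequence(
    candidates: list[ChainCandidate], sequence: ProteinSequence
) -> list[ChainCandidate]:
    """Annotate candidates with all (1-based, overlapping) match positions.

    Candidates absent from the sequence get empty positions and are thereby
    marked discarded; they stay in the list for reporting.
    """
    text = sequence.residues
    for cand in candidates:
        positions = []
        start = text.find(cand.sequence)
        while start != -1:
            positions.append(start + 1)
            start = text.find(cand.sequence, start + 1)
        cand.positions = positions
    return candidates


@dataclass
class ChainMapping:
    chain_id: str
    candidates: list[ChainCandidate]

    @property
    def survivors(self) -> list[ChainCandidate]:
        return [c for c in self.candidates if not c.discarded]

    @property
    def unambiguous(self) -> bool:
        """Exactly one surviving candidate with exactly one sequence position."""
        return len(self.survivors) == 1 and len(self.survivors[0].positions) == 1

    def report_rows(self) -> list[dict]:
        rows = []
        for cand in self.candidates:
            rows.append(
                {
                    "chain_id": self.chain_id,
                    "candidate_sequence": cand.sequence,
                    "joint_probability": cand.joint_probability,
                    "positions": ";".join(str(p) for p in cand.positions),
                    "discarded": cand.discarded,
                }
            )
        return rows


def map_chain(
    chain: Chain,
    training: list[SpinSystem],
    subset: ShiftSubset,
    sequence: ProteinSequence,
    allowed_types: set[str] | None = None,
    inclusion_threshold: float = DEFAULT_INCLUSION_THRESHOLD,
    top_types: int = DEFAULT_TOP_TYPES,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> ChainMapping:
    """Classify, enumerate, and sequence-filter one chain.

    An empty survivor set is a valid outcome (reported, requiring manual
    intervention); it is not an error.
    """
    candidates = enumerate_candidates(
        chain, training, subset, allowed_types,
        inclusion_threshold, top_types, max_candidates,
    )
    filter_by_sequence(candidates, sequence)
    if not any(not c.discarded for c in candidates):
        logger.warning(
            "chain %s: no candidate matches the sequence; manual intervention needed",
            chain.id,
        )
    return ChainMapping(chain.id, candidates)


def manual_baseline(chain: Chain) -> list[str]:
    """Coarse by-eye typing: G, A, S, T or X per position (pre included).

    Glycine is called from the structural absence of beta shifts; A/S/T
    from characteristic CB windows; everything else is X.
    """
    members = ([chain.pre] if chain.pre is not None else []) + list(chain.members)
    out = []
    for ss in members:
        if "CA" in ss.shifts and "CB" not in ss.shifts and "HB" not in ss.shifts:
            out.append("G")
            continue
        cb = ss.shifts.get("CB")
        call = "X"
        if cb is not None:
            for res, (lo, hi) in _MANUAL_CB_WINDOWS.items():
                if lo <= cb <= hi:
                    call = res
                    break
        out.append(call)
    return out


def structural_exclusions(spin: SpinSystem) -> set[str]:
    """Residue types ruled out by the structure of the observed shifts.

    Any beta shift excludes glycine; two distinct HB values exclude the
    types without chemically inequivalent beta protons (A, I, T, V).
    """
    excluded: set[str] = set()
    if "CB" in spin.shifts or "HB" in spin.shifts:
        excluded.add("G")
    raw = spin.raw_shifts or {}
    hb_values = {v for k, v in raw.items() if k.startswith("HB")}
    if len(hb_values) >= 2:
        excluded |= {"A", "I", "T", "V"}
    return excluded


def apply_exclusions(
    probabilities: dict[str, float], excluded: set[str]
) -> dict[str, float]:
    """Zero out excluded classes and renormalize."""
    masked = {t: (0.0 if t in excluded else p) for t, p in probabilities.items()}
    total = sum(masked.values())
    if total <= 0:
        return probabilities
    return {t: p / total for t, p in masked.items()}
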