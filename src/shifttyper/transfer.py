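"""Assignment transfer between 2D (H, N) peak lists.

Reference peaks carry labels such as ``Y39N-H`` or ``Y39-V40`` from which
the *preceding* residue type is derived (for an amide peak of residue i,
the side-chain shifts measured through the carbonyl belong to residue
i-1).  Each experimental peak is associated with a spin system holding
those preceding-residue shifts; the classifier's posterior for the
reference's preceding type, together with spatial proximity, drives the
matching.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

from . import lda
from .types import Peak2D, ShiftSubset, SpinSystem, one_letter

logger = logging.getLogger(__name__)

DEFAULT_H_SCALE = 1.0
DEFAULT_N_SCALE = 5.0
DEFAULT_H_RADIUS = 0.1
DEFAULT_N_RADIUS = 0.5

_PAIR_LABEL = re.compile(r"^([A-Za-z]{1,3})(\d+)(?:-|N-H|NH)?")


def preceding_type_from_label(label: str) -> str | None:
    """Preceding residue type encoded in a reference label.

    ``Y39-V40`` → Y (the first residue of the pair precedes the second);
    ``V40N-H`` → None (no information about residue 39 in the label alone).
    A bare pair form is required; otherwise None is returned.
    """
    if "-" in label:
        first = label.split("-")[0]
        m = _PAIR_LABEL.match(first)
        second = label.split("-", 1)[1]
        if m and re.match(r"^[A-Za-z]{1,3}\d+", second):
            try:
                return one_letter(m.group(1))
            except ValueError:
                return None
    return None


@dataclass
class TransferMatch:
    reference: Peak2D
    experimental: Peak2D | None
    distance: float | None
    class_consistent: bool
    lda_probability: float
    ambiguity_flag: bool
    candidates: list[dict]
    """Full ranked candidate table for the reference peak."""


def _scaled_distance(a: Peak2D, b: Peak2D, h_scale: float, n_scale: float) -> float:
    return math.hypot(
        (a.h_ppm - b.h_ppm) / h_scale, (a.n_ppm - b.n_ppm) / n_scale
    )


def transfer_assignments(
    reference: list[Peak2D],
    experimental: list[Peak2D],
    experimental_spins: dict[int, SpinSystem],
    training: list[SpinSystem],
    subset: ShiftSubset,
    allowed_types: set[str] | None = None,
    h_radius: float = DEFAULT_H_RADIUS,
    n_radius: float = DEFAULT_N_RADIUS,
    h_scale: float = DEFAULT_H_SCALE,
    n_scale: float = DEFAULT_N_SCALE,
    precomputed_probabilities: list[dict[str, float]] | None = None,
) -> list[TransferMatch]:
    """Match reference peaks to experimental peaks, one-to-one.

    ``experimental_spins`` maps experimental-peak index to the spin system
    of its preceding residue.  Candidates within the per-axis radius are
    ranked by (class-consistency, classifier posterior, -distance);
    assignments are made greedily over reference peaks in order of
    decreasing best-candidate margin, each experimental peak used at most
    once.  A match is flagged ambiguous when two or more class-consistent
    candidates exist.
    """
    if precomputed_probabilities is not None:
        probs_per_exp = list(precomputed_probabilities)
    else:
        indices = sorted(experimental_spins)
        spins = [experimental_spins[i] for i in indices]
        results = lda.classify_batch(spins, training, subset, allowed_types)
        by_index = {i: r.probabilities for i, r in zip(indices, results)}
        probs_per_exp = [by_index.get(i, {}) for i in range(len(experimental))]

    pending: list[tuple[float, int, list[dict]]] = []  # (-margin, ref idx, candidates)
    for ri, ref in enumerate(reference):
        if ref.label is None:
            continue
        target_type = preceding_type_from_label(ref.label)
        if target_type is None:
            logger.warning("reference peak %r: label not parsable; skipped", ref.label)
            continue
        candidates = []
        for ei, exp in enumerate(experimental):
            if abs(ref.h_ppm - exp.h_ppm) > h_radius or abs(ref.n_ppm - exp.n_ppm) > n_radius:
                continue
            probs = probs_per_exp[ei] if ei < len(probs_per_exp) else {}
            p_target = probs.get(target_type, 0.0)
            predicted = max(probs, key=probs.get) if probs else None
            candidates.append(
                {
                    "exp_index": ei,
                    "distance": _scaled_distance(ref, exp, h_scale, n_scale),
                    "class_consistent": predicted == target_type,
                    "lda_probability": p_target,
                    "predicted_type": predicted,
                    "target_type": target_type,
                }
            )
        candidates.sort(
            key=lambda c: (
                not c["class_consistent"],
                -c["lda_probability"],
                c["distance"],
            )
        )
        if not candidates:
            pending.append((math.inf, ri, candidates))
            continue
        if len(candidates) == 1:
            margin = math.inf
        else:
            margin = candidates[0]["lda_probability"] - candidates[1]["lda_probability"]
        pending.append((-margin, ri, candidates))

    pending.sort(key=lambda t: (t[0], t[1]))
    used: set[int] = set()
    matches: dict[int, TransferMatch] = {}
    for _, ri, candidates in pending:
        ref = reference[ri]
        available = [c for c in candidates if c["exp_index"] not in used]
        n_consistent = sum(1 for c in available if c["class_consistent"])
        if not available:
            matches[ri] = TransferMatch(
                ref, None, None, False, 0.0, False, candidates
            )
            continue
        best = available[0]
        used.add(best["exp_index"])
        matches[ri] = TransferMatch(
            reference=ref,
            experimental=experimental[best["exp_index"]],
            distance=best["distance"],
            class_consistent=best["class_consistent"],
            lda_probability=best["lda_probability"],
            ambiguity_flag=n_consistent >= 2,
            candidates=candidates,
        )
    return [matches[ri] for ri in sorted(matches)]
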