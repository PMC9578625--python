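"""Study protocol: cross-validation, confusion charts, feature importance.

Leave-one-out runs at the *protein* level: the classifier is trained on all
but one protein and tested on the held-out one, cycling through every
protein.  Accuracy is the fraction of correct residue-type calls, and the
summary is the mean over proteins weighted by the number of residues each
contributed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import lda
from .types import ShiftSubset, SpinSystem

logger = logging.getLogger(__name__)


@dataclass
class LooResult:
    per_protein_accuracy: dict[str, float]
    per_protein_count: dict[str, int]
    weighted_mean_accuracy: float
    predictions: dict[str, list[tuple[str, str, str]]]
    """Per protein: (spin system id, true type, predicted type)."""


@dataclass
class ConfusionChart:
    classes: list[str]
    row_counts: dict[str, int]
    matrix: np.ndarray  # row-normalized fractions, rows = true types


@dataclass
class ImportanceResult:
    shift_names: tuple[str, ...]
    baseline_error: float
    mean_error: dict[str, float]
    sd_error: dict[str, float]
    n_repeats: int
    seed: int

    def ranking(self) -> list[str]:
        """Shift names sorted by decreasing mean error (most important first)."""
        return sorted(self.mean_error, key=self.mean_error.get, reverse=True)


def _eligible(ss: SpinSystem, subset: ShiftSubset, mode: str) -> bool:
    if not ss.present(subset.shift_names):
        return False
    if mode == "restricted":
        return True
    if mode == "complete":
        # natural absences (Gly CB/HB, Pro HN) do not disqualify a residue
        return ss.is_complete_for(subset.shift_names, respect_natural_absence=True)
    raise ValueError(f"unknown mode {mode!r}; use 'restricted' or 'complete'")


def leave_one_out(
    proteins: dict[str, list[SpinSystem]],
    subset: ShiftSubset,
    mode: str = "restricted",
) -> LooResult:
    """Protein-level leave-one-out cross-validation.

    ``mode='restricted'`` scores every labeled spin system, routing
    incomplete ones through restricted models; ``mode='complete'`` scores
    only spin systems complete for the subset (modulo Gly/Pro natural
    absences).  Training residue types are limited to the types present in
    the held-out protein, and train/test values are Pareto-scaled jointly.
    """
    if len(proteins) < 2:
        raise ValueError("leave-one-out needs at least 2 proteins")
    per_acc: dict[str, float] = {}
    per_n: dict[str, int] = {}
    predictions: dict[str, list[tuple[str, str, str]]] = {}
    for held_out in proteins:
        test = [
            ss for ss in proteins[held_out]
            if ss.residue_type is not None and _eligible(ss, subset, mode)
        ]
        if not test:
            logger.warning("protein %s: no classifiable spin systems; excluded", held_out)
            continue
        training = [
            ss for name, group in proteins.items() if name != held_out for ss in group
        ]
        allowed = {ss.residue_type for ss in test}
        results = lda.classify_batch(test, training, subset, allowed)
        triples = [
            (ss.id, ss.residue_type, res.predicted) for ss, res in zip(test, results)
        ]
        correct = sum(1 for _, t, p in triples if t == p)
        per_acc[held_out] = correct / len(triples)
        per_n[held_out] = len(triples)
        predictions[held_out] = triples
    total = sum(per_n.values())
    weighted = sum(per_acc[p] * per_n[p] for p in per_acc) / total
    return LooResult(per_acc, per_n, weighted, predictions)


def confusion_chart(true_types, predicted_types) -> ConfusionChart:
    """Row-normalized confusion matrix over alphabetically ordered classes."""
    true_types = list(true_types)
    predicted_types = list(predicted_types)
    if len(true_types) != len(predicted_types):
        raise ValueError("label lists must have equal length")
    classes = sorted(set(true_types) | set(predicted_types))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    for t, p in zip(true_types, predicted_types):
        counts[index[t], index[p]] += 1
    row_totals = counts.sum(axis=1)
    matrix = np.divide(
        counts,
        row_totals[:, None],
        out=np.zeros_like(counts),
        where=row_totals[:, None] > 0,
    )
    return ConfusionChart(
        classes=classes,
        row_counts={c: int(row_totals[index[c]]) for c in classes},
        matrix=matrix,
    )


def permutation_importance(
    table: lda.TrainingTable,
    n_repeats: int = 1000,
    seed: int = 0,
) -> ImportanceResult:
    """Column-shuffle feature importance.

    The model is trained once on the intact (Pareto-scaled) table.  For
    each column and repeat, that single column of a copy of the table is
    shuffled and every row re-classified with the intact model; the error
    rate (1 - accuracy) is recorded.  Reported are the per-column mean and
    standard deviation over repeats.
    """
    rng = np.random.default_rng(seed)
    state = lda.pareto_scaling_state(table.values, None, table.shift_names)
    scaled = lda.TrainingTable(
        table.shift_names, state.transform(table.values), table.labels
    )
    model = lda.fit(scaled, state)
    labels = np.asarray(table.labels, dtype=object)
    class_index = {c: i for i, c in enumerate(model.classes)}
    y = np.array([class_index[lab] for lab in labels])

    def error_rate(values: np.ndarray) -> float:
        pred = model.discriminant_scores(values).argmax(axis=1)
        return float(np.mean(pred != y))

    baseline = error_rate(scaled.values)
    mean_err: dict[str, float] = {}
    sd_err: dict[str, float] = {}
    for j, name in enumerate(table.shift_names):
        errors = np.empty(n_repeats)
        work = scaled.values.copy()
        for r in range(n_repeats):
            work[:, j] = rng.permutation(scaled.values[:, j])
            errors[r] = error_rate(work)
        work[:, j] = scaled.values[:, j]
        mean_err[name] = float(errors.mean())
        sd_err[name] = float(errors.std())
    return ImportanceResult(
        shift_names=table.shift_names,
        baseline_error=baseline,
        mean_error=mean_err,
        sd_error=sd_err,
        n_repeats=n_repeats,
        seed=seed,
    )
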