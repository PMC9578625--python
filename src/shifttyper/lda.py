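"""Linear (and quadratic) discriminant classification of spin systems.

The classifier models each residue type's chemical shifts as a multivariate
normal with a class mean and a covariance shared across classes (the pooled
covariance).  Class statistics use the population (1/n_k) normalization;
the pooled covariance is the class-count-weighted average

    Sigma_pooled = (1/N) * sum_k n_k * Sigma_k

and the per-class linear score for a query vector x is

    f_k(x) = mu_k^T Sigma_pooled^-1 x
             - 1/2 mu_k^T Sigma_pooled^-1 mu_k + ln(pi_k)

with priors pi_k = n_k / N.  Posterior probabilities are the softmax of the
scores, which is exactly the Gaussian posterior under the shared-covariance
model.

Columns are normalized by *Pareto scaling* — mean-centering followed by
division by the square root of the (population) standard deviation —
computed jointly over training and query values so that referencing offsets
between data sets cancel.

Incomplete query spin systems are handled by *restricted models*: a fresh
classifier trained on only the columns the query carries, using only
training spin systems complete for those columns.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .types import NATURALLY_ABSENT, ShiftSubset, SpinSystem

logger = logging.getLogger(__name__)

#: Regularization ladder: lambda * mean(diag) * I added to a covariance that
#: is not positive definite, escalating by decades before giving up.
_REG_LAMBDAS = (1e-6, 1e-5, 1e-4, 1e-3)


class ZeroVarianceError(ValueError):
    """A column has no variance, so Pareto scaling is undefined."""


@dataclass
class ScalingState:
    """Per-column center and divisor applied to shift values."""

    shift_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            bad = [self.shift_names[i] for i in np.nonzero(self.scale <= 0)[0]]
            raise ZeroVarianceError(f"non-positive scale for columns {bad}")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) / self.scale

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.scale + self.center


def pareto_scaling_state(
    train_values: np.ndarray,
    test_values: np.ndarray | None,
    shift_names: tuple[str, ...],
) -> ScalingState:
    """Compute joint Pareto scaling over training plus query values.

    For each column the center is the mean of the concatenated training and
    query values and the divisor is the square root of their population
    standard deviation.
    """
    if test_values is not None and len(test_values):
        combined = np.vstack([train_values, np.asarray(test_values, dtype=float)])
    else:
        combined = np.asarray(train_values, dtype=float)
    center = combined.mean(axis=0)
    sd = combined.std(axis=0)  # population (ddof=0)
    if np.any(sd <= 0):
        bad = [shift_names[i] for i in np.nonzero(sd <= 0)[0]]
        raise ZeroVarianceError(f"zero variance in column(s) {bad}")
    return ScalingState(tuple(shift_names), center, np.sqrt(sd))


@dataclass
class TrainingTable:
    """A complete N x M matrix of shift values with residue-type labels."""

    shift_names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray
    subset: ShiftSubset | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.shift_names):
            raise ValueError("values must be N x M with M = len(shift_names)")
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("training table contains non-finite entries")
        counts = Counter(self.labels)
        small = sorted(k for k, n in counts.items() if n < 2)
        if small:
            raise ValueError(f"classes with fewer than 2 members: {small}")

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(sorted(Counter(self.labels).items()))

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_spin_systems(
        cls,
        spins: list[SpinSystem],
        shift_names,
        allowed_types: set[str] | None = None,
        subset: ShiftSubset | None = None,
    ) -> "TrainingTable":
        """Assemble a complete table from spin systems.

        Rows lacking any required shift are excluded, as are rows whose
        residue type is not in ``allowed_types``.  Residue types left with
        fewer than 2 rows are dropped with a warning (a covariance needs at
        least two samples).
        """
        shift_names = tuple(shift_names)
        rows, labels = [], []
        for ss in spins:
            if ss.residue_type is None:
                continue
            if allowed_types is not None and ss.residue_type not in allowed_types:
                continue
            if not all(s in ss.shifts for s in shift_names):
                continue
            rows.append([ss.shifts[s] for s in shift_names])
            labels.append(ss.residue_type)
        counts = Counter(labels)
        small = {k for k, n in counts.items() if n < 2}
        if small:
            logger.warning(
                "dropping residue types with <2 complete training rows: %s",
                sorted(small),
            )
            keep = [i for i, lab in enumerate(labels) if lab not in small]
            rows = [rows[i] for i in keep]
            labels = [labels[i] for i in keep]
        if not rows:
            raise ValueError(
                f"no training rows complete for columns {shift_names}"
            )
        return cls(shift_names, np.array(rows, float), np.array(labels, object), subset)


def pareto_scale(
    table: TrainingTable, test: list[SpinSystem]
) -> tuple[TrainingTable, list[SpinSystem], ScalingState]:
    """Jointly Pareto-scale a training table and query spin systems.

    Query shifts outside the table's columns are left untouched.  Returns
    scaled copies plus the state needed to scale further queries identically.
    """
    cols = table.shift_names
    test_rows = [
        [ss.shifts[c] for c in cols] for ss in test if all(c in ss.shifts for c in cols)
    ]
    state = pareto_scaling_state(
        table.values, np.array(test_rows, float) if test_rows else None, cols
    )
    scaled_table = TrainingTable(
        cols, state.transform(table.values), table.labels.copy(), table.subset
    )
    scaled_test = []
    for ss in test:
        shifts = dict(ss.shifts)
        for j, c in enumerate(cols):
            if c in shifts:
                shifts[c] = (shifts[c] - state.center[j]) / state.scale[j]
        scaled_test.append(
            SpinSystem(ss.id, shifts, ss.residue_type, ss.source, ss.sequence_position)
        )
    return scaled_table, scaled_test, state


def fit_class_stats(
    table: TrainingTable,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-class means and population covariances.

    Returns ``(classes, means, covs)`` where ``classes`` is alphabetical,
    ``means`` is K x M and ``covs`` is K x M x M, each covariance computed
    with the 1/n_k normalization.
    """
    classes = sorted(set(table.labels))
    M = len(table.shift_names)
    means = np.empty((len(classes), M))
    covs = np.empty((len(classes), M, M))
    for k, cls_ in enumerate(classes):
        rows = table.values[table.labels == cls_]
        if len(rows) < 2:
            raise ValueError(f"class {cls_!r} has fewer than 2 members")
        means[k] = rows.mean(axis=0)
        centered = rows - means[k]
        covs[k] = centered.T @ centered / len(rows)
    return classes, means, covs


def pooled_covariance(
    per_class_cov: np.ndarray, class_counts: np.ndarray, n_total: int
) -> np.ndarray:
    """Class-count-weighted average covariance, symmetrized."""
    counts = np.asarray(class_counts, dtype=float)
    if int(counts.sum()) != n_total:
        raise ValueError("class counts do not sum to N")
    pooled = np.tensordot(counts, per_class_cov, axes=1) / n_total
    return (pooled + pooled.T) / 2.0


def _ensure_positive_definite(mat: np.ndarray, context: str = "covariance") -> np.ndarray:
    """Return ``mat`` (or a regularized copy) that admits a Cholesky factor."""
    mat = (mat + mat.T) / 2.0
    try:
        np.linalg.cholesky(mat)
        return mat
    except np.linalg.LinAlgError:
        pass
    base = np.mean(np.diag(mat))
    if base <= 0:
        base = 1.0
    eye = np.eye(mat.shape[0])
    for lam in _REG_LAMBDAS:
        candidate = mat + lam * base * eye
        try:
            np.linalg.cholesky(candidate)
            logger.debug("regularized %s with lambda=%g", context, lam)
            return candidate
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(f"{context} not positive definite after regularization")


@dataclass
class LdaModel:
    """A fitted shared-covariance Gaussian classifier."""

    shift_names: tuple[str, ...]
    classes: list[str]
    means: np.ndarray          # K x M, in scaled units
    pooled_cov: np.ndarray     # M x M
    pooled_cov_inv: np.ndarray
    priors: np.ndarray         # K
    scaling: ScalingState
    per_class_cov: np.ndarray | None = None  # K x M x M, for QDA
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors do not sum to 1")

    def discriminant_scores(self, x: np.ndarray) -> np.ndarray:
        """Linear scores f_k(x) for scaled query vector(s).

        ``x`` may be a single M-vector or an (n, M) matrix; returns shape
        (K,) or (n, K) accordingly.
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != len(self.shift_names):
            raise ValueError(
                f"query has {X.shape[1]} features, model expects {len(self.shift_names)}"
            )
        A = self.means @ self.pooled_cov_inv           # K x M
        const = -0.5 * np.einsum("km,km->k", A, self.means) + np.log(self.priors)
        scores = X @ A.T + const                        # n x K
        return scores[0] if single else scores

    def qda_scores(self, x: np.ndarray) -> np.ndarray:
        """Quadratic scores using per-class covariances.

        log-density plus log-prior:
        -1/2 ln|Sigma_k| - 1/2 (x-mu_k)^T Sigma_k^-1 (x-mu_k) + ln pi_k.
        """
        if self.per_class_cov is None:
            raise ValueError("model was fitted without per-class covariances")
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        out = np.empty((len(X), len(self.classes)))
        for k, cls_ in enumerate(self.classes):
            cov = _ensure_positive_definite(self.per_class_cov[k], f"class {cls_}")
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError(f"singular covariance for class {cls_}")
            diff = X - self.means[k]
            maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
            out[:, k] = -0.5 * logdet - 0.5 * maha + np.log(self.priors[k])
        return out[0] if single else out

    def predict(self, x: np.ndarray, method: str = "lda") -> list[str]:
        scores = self.discriminant_scores(x) if method == "lda" else self.qda_scores(x)
        scores = np.atleast_2d(scores)
        # argmax returns the first (alphabetically earliest) class on ties
        return [self.classes[i] for i in scores.argmax(axis=1)]

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "shifttyper-lda-model",
            "version": 1,
            "shift_names": list(self.shift_names),
            "classes": self.classes,
            "means": self.means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "priors": self.priors.tolist(),
            "class_counts": self.class_counts,
            "scaling": {
                "center": self.scaling.center.tolist(),
                "scale": self.scaling.scale.tolist(),
            },
            "per_class_cov": (
                self.per_class_cov.tolist() if self.per_class_cov is not None else None
            ),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LdaModel":
        doc = json.loads(text)
        if doc.get("format") != "shifttyper-lda-model":
            raise ValueError("not a shifttyper model document")
        shift_names = tuple(doc["shift_names"])
        pooled = np.array(doc["pooled_cov"], float)
        return cls(
            shift_names=shift_names,
            classes=list(doc["classes"]),
            means=np.array(doc["means"], float),
            pooled_cov=pooled,
            pooled_cov_inv=np.linalg.inv(_ensure_positive_definite(pooled)),
            priors=np.array(doc["priors"], float),
            scaling=ScalingState(
                shift_names,
                np.array(doc["scaling"]["center"], float),
                np.array(doc["scaling"]["scale"], float),
            ),
            per_class_cov=(
                np.array(doc["per_class_cov"], float)
                if doc.get("per_class_cov") is not None
                else None
            ),
            class_counts={k: int(v) for k, v in doc.get("class_counts", {}).items()},
        )


def posterior_probabilities(scores: np.ndarray) -> np.ndarray:
    """Stable softmax over the last axis."""
    scores = np.asarray(scores, dtype=float)
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def fit(table: TrainingTable, scaling: ScalingState, keep_per_class: bool = True) -> LdaModel:
    """Fit the classifier on an (already scaled) complete training table."""
    classes, means, covs = fit_class_stats(table)
    counts = np.array([np.sum(table.labels == c) for c in classes])
    pooled = pooled_covariance(covs, counts, table.n)
    pooled = _ensure_positive_definite(pooled, "pooled covariance")
    priors = counts / table.n
    return LdaModel(
        shift_names=table.shift_names,
        classes=classes,
        means=means,
        pooled_cov=pooled,
        pooled_cov_inv=np.linalg.inv(pooled),
        priors=priors,
        scaling=ScalingState(
            table.shift_names, np.zeros(len(table.shift_names)), np.ones(len(table.shift_names))
        ) if scaling is None else scaling,
        per_class_cov=covs if keep_per_class else None,
        class_counts={c: int(n) for c, n in zip(classes, counts)},
    )


def fit_restricted(
    full_training: list[SpinSystem],
    present_shifts,
    allowed_types: set[str] | None,
    query_values: np.ndarray | None = None,
) -> LdaModel:
    """Train a fresh model on only the given columns.

    Only training spin systems carrying all of ``present_shifts`` (and whose
    type is allowed) contribute.  Pareto scaling is recomputed jointly on
    the restricted table plus ``query_values`` (rows over the same columns).
    """
    present = tuple(present_shifts)
    if not present:
        raise ValueError("present_shifts must be non-empty")
    table = TrainingTable.from_spin_systems(full_training, present, allowed_types)
    if allowed_types is not None:
        missing = set(allowed_types) - set(table.class_counts)
        # Gly/Pro cannot appear in tables requiring their naturally absent
        # shifts; that is expected, not worth a warning per call
        structural = {
            t for t in missing if NATURALLY_ABSENT.get(t, frozenset()) & set(present)
        }
        if missing - structural:
            logger.warning(
                "allowed residue types with no usable training rows for columns "
                "%s: %s", present, sorted(missing - structural)
            )
        elif structural:
            logger.debug(
                "types structurally absent for columns %s: %s",
                present, sorted(structural),
            )
    state = pareto_scaling_state(table.values, query_values, present)
    scaled = TrainingTable(present, state.transform(table.values), table.labels)
    return fit(scaled, state)


@dataclass
class Classification:
    """Result of classifying one spin system."""

    spin_system_id: str
    scores: dict[str, float]
    probabilities: dict[str, float]
    predicted: str
    shifts_used: tuple[str, ...]


def _classification_from(model: LdaModel, ss_id: str, x_scaled: np.ndarray) -> Classification:
    scores = model.discriminant_scores(x_scaled)
    probs = posterior_probabilities(scores)
    pred = model.classes[int(np.argmax(scores))]
    return Classification(
        spin_system_id=ss_id,
        scores=dict(zip(model.classes, scores.tolist())),
        probabilities=dict(zip(model.classes, probs.tolist())),
        predicted=pred,
        shifts_used=model.shift_names,
    )


def classify_batch(
    queries: list[SpinSystem],
    training: list[SpinSystem],
    subset: ShiftSubset,
    allowed_types: set[str] | None = None,
) -> list[Classification]:
    """Classify spin systems, grouping by missingness pattern.

    Queries sharing a pattern of present shifts are scaled jointly with the
    restricted training table (training and test values normalized
    simultaneously), mirroring how a whole test protein is processed.
    """
    groups: dict[tuple[str, ...], list[int]] = {}
    for i, q in enumerate(queries):
        present = q.present(subset.shift_names)
        if not present:
            raise ValueError(
                f"spin system {q.id!r} has no usable shifts for subset {subset.name!r}"
            )
        groups.setdefault(present, []).append(i)
    results: list[Classification | None] = [None] * len(queries)
    for present, idxs in groups.items():
        values = np.array(
            [[queries[i].shifts[s] for s in present] for i in idxs], float
        )
        model = fit_restricted(training, present, allowed_types, values)
        scaled = model.scaling.transform(values)
        for row, i in enumerate(idxs):
            results[i] = _classification_from(model, queries[i].id, scaled[row])
    return results  # type: ignore[return-value]


def classify(
    query: SpinSystem,
    training: list[SpinSystem],
    subset: ShiftSubset,
    allowed_types: set[str] | None = None,
) -> Classification:
    """Classify a single spin system through the appropriate restricted model."""
    return classify_batch([query], training, subset, allowed_types)[0]
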