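"""Synthetic data generation for testing and simulation.

Shifts are drawn from class-conditional multivariate normals per residue
type, with structural missingness applied (glycine lacks beta shifts,
proline lacks the amide proton).  All generators are pure functions of
their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .types import (
    AMINO_ACIDS,
    CANONICAL_SHIFTS,
    NATURALLY_ABSENT,
    Chain,
    Peak2D,
    ProteinSequence,
    SpinSystem,
)


@dataclass
class ClassModel:
    """Per-residue-type shift means and covariances for sampling.

    ``means[r]`` maps shift names to ppm values (naturally absent shifts
    are simply missing); ``covs[r]`` is the covariance over that residue's
    shift names, in the order given by ``shift_order(r)``.
    """

    means: dict[str, dict[str, float]]
    covs: dict[str, np.ndarray]
    frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frequencies:
            self.frequencies = {r: 1.0 / len(self.means) for r in self.means}
        total = sum(self.frequencies.values())
        if not np.isclose(total, 1.0):
            raise ValueError("class frequencies must sum to 1")
        for r, cov in self.covs.items():
            cov = np.asarray(cov, dtype=float)
            eigmin = np.linalg.eigvalsh((cov + cov.T) / 2).min()
            if eigmin <= 0:
                raise ValueError(f"covariance for {r!r} is not positive definite")
            self.covs[r] = cov
        for r in self.means:
            absent = NATURALLY_ABSENT.get(r, frozenset())
            if absent & self.means[r].keys():
                raise ValueError(f"{r!r} must not have means for {sorted(absent)}")

    def shift_order(self, residue: str) -> tuple[str, ...]:
        return tuple(s for s in CANONICAL_SHIFTS if s in self.means[residue])


def default_class_model(
    sd_scale: float = 1.0,
    frequencies: dict[str, float] | None = None,
) -> ClassModel:
    """The 20-class fixture model shipped as package data.

    ``sd_scale`` scales every standard deviation, letting tests dial class
    separation up (small values) or down.
    """
    text = resources.files("shifttyper.data").joinpath(
        "synthetic_class_model.json"
    ).read_text()
    doc = json.loads(text)
    means = {r: dict(m) for r, m in doc["means"].items()}
    sds = doc["default_sd"]
    covs = {}
    for r, m in means.items():
        order = [s for s in CANONICAL_SHIFTS if s in m]
        covs[r] = np.diag([(sds[s] * sd_scale) ** 2 for s in order])
    return ClassModel(means, covs, frequencies or {})


def sample_protein(
    model: ClassModel,
    length: int,
    seed: int,
    missing_rate: float = 0.0,
) -> tuple[ProteinSequence, list[SpinSystem]]:
    """Draw a sequence from the class frequencies and shifts per residue.

    ``missing_rate`` removes each present shift independently with the
    given probability (on top of structural missingness), but never leaves
    a spin system empty.
    """
    rng = np.random.default_rng(seed)
    residues = sorted(model.means)
    freqs = np.array([model.frequencies[r] for r in residues])
    seq = rng.choice(residues, size=length, p=freqs / freqs.sum())
    spin_systems = []
    for pos, res in enumerate(seq, start=1):
        order = model.shift_order(res)
        mean = np.array([model.means[res][s] for s in order])
        values = rng.multivariate_normal(mean, model.covs[res])
        shifts = dict(zip(order, values.tolist()))
        if missing_rate > 0:
            keep = {s: v for s, v in shifts.items() if rng.random() >= missing_rate}
            if not keep:  # keep at least one shift
                survivor = order[rng.integers(len(order))]
                keep = {survivor: shifts[survivor]}
            shifts = keep
        spin_systems.append(
            SpinSystem(
                id=f"ss{pos}",
                shifts=shifts,
                residue_type=res,
                source="synthetic",
                sequence_position=pos,
            )
        )
    return ProteinSequence("synthetic", "".join(seq)), spin_systems


def sample_chains(
    sequence: ProteinSequence,
    spin_systems: list[SpinSystem],
    n_chains: int,
    length_range: tuple[int, int],
    seed: int,
    amide_mode: bool = True,
) -> list[Chain]:
    """Sample contiguous runs of spin systems as chains.

    In amide-detection mode no chain crosses a proline position (prolines
    interrupt amide-detected connectivity).
    """
    rng = np.random.default_rng(seed)
    by_pos = {ss.sequence_position: ss for ss in spin_systems}
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    # admissible (start, length) windows
    windows = []
    for length in range(lo, hi + 1):
        for start in range(1, len(sequence) - length + 2):
            span = sequence.residues[start - 1:start - 1 + length]
            if amide_mode and "P" in span:
                continue
            if all(p in by_pos for p in range(start, start + length)):
                windows.append((start, length))
    if not windows:
        raise ValueError("no admissible chain window; relax the length range")
    chains = []
    for i in range(n_chains):
        start, length = windows[rng.integers(len(windows))]
        members = [by_pos[p] for p in range(start, start + length)]
        pre = by_pos.get(start - 1)
        chains.append(Chain(id=f"chain{i + 1}", members=members, pre=pre))
    return chains


def peaks_from_spin_systems(spin_systems: list[SpinSystem]) -> list[Peak2D]:
    """Labeled (H, N) peaks for every spin system carrying both shifts."""
    peaks = []
    for ss in spin_systems:
        if "HN" in ss.shifts and "N" in ss.shifts:
            label = ss.id
            if ss.residue_type and ss.sequence_position:
                label = f"{ss.residue_type}{ss.sequence_position}N-H"
            peaks.append(Peak2D(label, ss.shifts["HN"], ss.shifts["N"]))
    return peaks


def jitter_peaks(
    peaks: list[Peak2D], h_sd: float, n_sd: float, seed: int
) -> list[Peak2D]:
    """Gaussian per-axis jitter, labels preserved."""
    rng = np.random.default_rng(seed)
    out = []
    for p in peaks:
        dh = rng.normal(0.0, h_sd) if h_sd > 0 else 0.0
        dn = rng.normal(0.0, n_sd) if n_sd > 0 else 0.0
        out.append(Peak2D(p.label, p.h_ppm + dh, p.n_ppm + dn))
    return out
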