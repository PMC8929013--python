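"""Synthetic datasets with planted, tunable class signal.

The generator emulates the structure of the published pseudouridine
benchmarks — balanced sets of fixed-length U-centered windows — with a
controllable position-specific nucleotide-composition bias separating the
classes. At designated signal positions, positive windows draw a
designated nucleotide with probability ``background + signal_strength``;
negative windows draw pure background. The signal is a composition bias
rather than a fixed motif so that both the position-sensitive encoders
(one-hot, NCP, PSKP) and the compositional ones (k-mer, KD, PseDNC)
receive partially independent signal, mirroring the heterogeneity that
makes the six-predictor ensemble effective.

A separate generator produces raw feature matrices with known informative
columns (Gaussian class shift) for feature-selection recovery tests, and
long background RNAs with planted positive windows for scanner tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .encoders import NUCLEOTIDES
from .sequences import LabeledDataset, RnaSequence, validate_dataset

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_dataset",
    "generate_informative_matrix",
    "generate_long_rna",
]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic benchmark-like dataset.

    Defaults: 100 positives + 100 negatives of length 21 with a strong
    (0.6 excess probability) G bias at four flanking positions — a signal
    strength at which single descriptors classify well above chance but
    below ceiling, so ensemble gains remain measurable.
    """

    n_pos: int = 100
    n_neg: int = 100
    window_length: int = 21
    signal_positions: tuple[int, ...] = (6, 8, 14, 16)  # 1-based, ≠ center
    signal_nucleotides: tuple[str, ...] = ("G", "G", "G", "G")
    signal_strength: float = 0.6
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        lam = self.window_length
        if lam % 2 == 0 or lam < 3:
            raise ValueError("window_length must be odd and ≥ 3")
        center = (lam + 1) // 2
        if any(p == center for p in self.signal_positions):
            raise ValueError(f"signal position {center} is the center U")
        if any(not 1 <= p <= lam for p in self.signal_positions):
            raise ValueError("signal positions must lie within the window")
        if len(self.signal_nucleotides) != len(self.signal_positions):
            raise ValueError("one designated nucleotide per signal position")
        if any(n not in NUCLEOTIDES for n in self.signal_nucleotides):
            raise ValueError("designated nucleotides must be A, U, C or G")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must lie in [0, 1]")
        if abs(sum(self.background) - 1) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        if self.signal_strength + max(self.background) > 1 + 1e-9:
            raise ValueError(
                "signal_strength + max background probability exceeds 1"
            )


@dataclass
class GroundTruth:
    """What was planted: positions, nucleotides, and the informative
    one-hot mononucleotide columns they induce."""

    signal_positions: tuple[int, ...]
    signal_nucleotides: tuple[str, ...]
    signal_strength: float
    informative_onehot_columns: tuple[int, ...] = field(default=())

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("position\tnucleotide\texcess_probability\n")
            for p, n in zip(self.signal_positions, self.signal_nucleotides):
                out.write(f"{p}\t{n}\t{self.signal_strength}\n")


def _draw_window(
    rng: np.random.Generator, spec: FixtureSpec, positive: bool
) -> str:
    lam = spec.window_length
    probs = np.tile(np.asarray(spec.background, dtype=float), (lam, 1))
    if positive and spec.signal_strength > 0:
        for pos, nt in zip(spec.signal_positions, spec.signal_nucleotides):
            row = probs[pos - 1].copy()
            k = NUCLEOTIDES.index(nt)
            p_designated = row[k] + spec.signal_strength
            rest = np.delete(np.arange(4), k)
            row[rest] *= (1 - p_designated) / row[rest].sum()
            row[k] = p_designated
            probs[pos - 1] = row
    cum = probs.cumsum(axis=1)
    draws = rng.uniform(size=lam)
    indices = (draws[:, None] > cum).sum(axis=1)
    residues = [NUCLEOTIDES[i] for i in indices]
    residues[lam // 2] = "U"
    return "".join(residues)


def generate_dataset(spec: FixtureSpec) -> tuple[LabeledDataset, GroundTruth]:
    """Draw a balanced labeled dataset per the fixture spec.

    Bit-reproducible from ``spec.seed``. The ground-truth record lists
    the informative one-hot mononucleotide columns (4·(p−1) + nucleotide
    index for each signal position) for selection-recovery experiments.
    """
    rng = np.random.default_rng(spec.seed)
    pos = [
        RnaSequence(f"pos_{i + 1}", _draw_window(rng, spec, True))
        for i in range(spec.n_pos)
    ]
    neg = [
        RnaSequence(f"neg_{i + 1}", _draw_window(rng, spec, False))
        for i in range(spec.n_neg)
    ]
    dataset = validate_dataset(pos, neg, spec.window_length)
    onehot_cols = tuple(
        4 * (p - 1) + NUCLEOTIDES.index(n)
        for p, n in zip(spec.signal_positions, spec.signal_nucleotides)
    )
    truth = GroundTruth(
        spec.signal_positions,
        spec.signal_nucleotides,
        spec.signal_strength,
        onehot_cols,
    )
    return dataset, truth


def generate_informative_matrix(
    n_samples: int = 120,
    n_informative: int = 10,
    n_noise: int = 90,
    effect: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw feature matrix with known informative columns.

    Balanced binary labels; informative columns are standard normal
    shifted by ``effect`` in the positive class, noise columns are pure
    standard normal. Returns (X, labels, informative column indices);
    column order is shuffled so informativeness is not positional.
    """
    rng = np.random.default_rng(seed)
    n_pos = n_samples // 2
    labels = np.concatenate(
        [np.ones(n_pos, dtype=int), np.zeros(n_samples - n_pos, dtype=int)]
    )
    n_total = n_informative + n_noise
    X = rng.standard_normal((n_samples, n_total))
    X[: n_pos, :n_informative] += effect
    order = rng.permutation(n_total)
    X = X[:, order]
    informative = np.where(np.isin(order, np.arange(n_informative)))[0]
    return X, labels, informative


def generate_long_rna(
    length: int,
    planted_windows: Sequence[tuple[int, RnaSequence]],
    seed: int = 0,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seq_id: str = "synthetic_rna",
) -> tuple[RnaSequence, list[int]]:
    """Background RNA with positive-class windows spliced in.

    ``planted_windows`` holds (1-based start position, window) pairs;
    windows must fit inside the sequence and must not overlap. Returns
    the sequence and the 1-based center positions of the plantings.
    """
    rng = np.random.default_rng(seed)
    residues = list(
        rng.choice(list(NUCLEOTIDES), size=length, p=np.asarray(background))
    )
    occupied: list[tuple[int, int]] = []
    centers = []
    for start, window in sorted(planted_windows, key=lambda pw: pw[0]):
        end = start + window.length - 1
        if start < 1 or end > length:
            raise ValueError(
                f"window at {start} (length {window.length}) exceeds "
                f"sequence length {length}"
            )
        for s, e in occupied:
            if start <= e and end >= s:
                raise ValueError(f"window at {start} overlaps window at {s}")
        occupied.append((start, end))
        residues[start - 1 : end] = list(window.residues)
        centers.append(start + window.length // 2)
    return RnaSequence(seq_id, "".join(residues)), centers
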