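"""Six sequence feature descriptors for U-centered RNA windows.

Descriptors and their dimensionality for a window of length λ:

======== ===========================================  ============
name     description                                  dimension
======== ===========================================  ============
ONEHOT   per-position mono- and dinucleotide           20λ − 16
         indicator bits
KMER     mono- and dinucleotide frequencies (k=1,2)    20
KD       k-nucleotide density: prefix-normalized       2λ − 1
         running count of the residue at each position
PSEDNC   pseudo dinucleotide composition: dinucleotide 16 + λ_pse
         frequencies + sequence-order correlation
         factors from physicochemical properties
PSKP     position-specific k-nucleotide propensity:    2λ − 1
         per-position frequency differences between
         site and non-site training sequences
NCP      nucleotide chemical property triplets         3λ
         (ring structure, functional group, hydrogen
         bond strength)
======== ===========================================  ============

All encoders share one canonical ordering: nucleotides A, U, C, G and
dinucleotides lexicographic over that order (AA, AU, AC, AG, UA, ..., GG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .sequences import LabeledDataset, RnaSequence

NUCLEOTIDES = "AUCG"
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
_DI_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

DESCRIPTORS = ("ONEHOT", "KMER", "KD", "PSEDNC", "PSKP", "NCP")

# Eq.-2 chemical property triplet (ring structure, functional group,
# hydrogen-bond strength) per nucleotide.
NCP_TABLE = {
    "A": (1, 1, 1),
    "U": (0, 0, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
}

__all__ = [
    "NUCLEOTIDES",
    "DINUCLEOTIDES",
    "DESCRIPTORS",
    "NCP_TABLE",
    "FeatureMatrix",
    "PropensityTable",
    "PseDncConfig",
    "EncoderError",
    "descriptor_dimension",
    "encode_one_hot",
    "encode_kmer",
    "encode_kd",
    "encode_ncp",
    "encode_psednc",
    "fit_pskp",
    "encode_pskp",
    "encode_dataset",
    "encode_sequences",
]


class EncoderError(ValueError):
    """Encoder precondition violated (length, configuration, fit state)."""


@dataclass
class FeatureMatrix:
    """Rows of one descriptor's feature vectors plus optional labels."""

    values: np.ndarray
    feature_names: list[str]
    descriptor: str
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise EncoderError("feature matrix must be 2-dimensional")
        if self.values.shape[1] != len(self.feature_names):
            raise EncoderError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != self.values.shape[0]:
                raise EncoderError("labels length != number of rows")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        frame = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            frame.insert(0, "label", self.labels)
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, descriptor: str) -> "FeatureMatrix":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t")
        labels = None
        if "label" in frame.columns:
            labels = frame.pop("label").to_numpy(dtype=int)
        return cls(
            frame.to_numpy(dtype=float), list(frame.columns), descriptor, labels
        )


def descriptor_dimension(
    descriptor: str, window_length: int, lambda_pse: int = 2
) -> int:
    """Feature-vector dimensionality of a descriptor at window length λ."""
    lam = window_length
    return {
        "ONEHOT": 20 * lam - 16,
        "KMER": 20,
        "KD": 2 * lam - 1,
        "PSEDNC": 16 + lambda_pse,
        "PSKP": 2 * lam - 1,
        "NCP": 3 * lam,
    }[descriptor.upper()]


def _require_length(seq: RnaSequence, minimum: int) -> None:
    if seq.length < minimum:
        raise EncoderError(
            f"{seq.seq_id}: length {seq.length} < required minimum {minimum}"
        )


def encode_one_hot(seq: RnaSequence) -> np.ndarray:
    """Indicator encoding: λ 4-bit mononucleotide blocks (order A,U,C,G)
    followed by λ−1 16-bit dinucleotide blocks; dimension 20λ−16."""
    lam = seq.length
    vec = np.zeros(20 * lam - 16)
    for i, nt in enumerate(seq.residues):
        vec[4 * i + _NT_INDEX[nt]] = 1.0
    offset = 4 * lam
    for i in range(lam - 1):
        di = seq.residues[i : i + 2]
        vec[offset + 16 * i + _DI_INDEX[di]] = 1.0
    return vec


def one_hot_feature_names(window_length: int) -> list[str]:
    names = [
        f"onehot_p{i + 1}_{nt}"
        for i in range(window_length)
        for nt in NUCLEOTIDES
    ]
    names += [
        f"onehot_p{i + 1}_{di}"
        for i in range(window_length - 1)
        for di in DINUCLEOTIDES
    ]
    return names


def encode_kmer(seq: RnaSequence) -> np.ndarray:
    """Mono- (k=1) and dinucleotide (k=2) occurrence frequencies; 20-dim."""
    _require_length(seq, 2)
    lam = seq.length
    mono = np.zeros(4)
    for nt in seq.residues:
        mono[_NT_INDEX[nt]] += 1
    di = np.zeros(16)
    for i in range(lam - 1):
        di[_DI_INDEX[seq.residues[i : i + 2]]] += 1
    return np.concatenate([mono / lam, di / (lam - 1)])


def kmer_feature_names() -> list[str]:
    return [f"kmer_{nt}" for nt in NUCLEOTIDES] + [
        f"kmer_{di}" for di in DINUCLEOTIDES
    ]


def encode_kd(seq: RnaSequence) -> np.ndarray:
    """k-nucleotide density: at each position i, the count of the residue
    observed there within the prefix 1..i, divided by i; the same prefix
    rule applied to dinucleotide positions. Dimension 2λ−1."""
    _require_length(seq, 2)
    lam = seq.length
    vec = np.empty(2 * lam - 1)
    counts = np.zeros(4)
    for i, nt in enumerate(seq.residues):
        counts[_NT_INDEX[nt]] += 1
        vec[i] = counts[_NT_INDEX[nt]] / (i + 1)
    di_counts = np.zeros(16)
    for i in range(lam - 1):
        k = _DI_INDEX[seq.residues[i : i + 2]]
        di_counts[k] += 1
        vec[lam + i] = di_counts[k] / (i + 1)
    return vec


def kd_feature_names(window_length: int) -> list[str]:
    return [f"kd_mono_p{i + 1}" for i in range(window_length)] + [
        f"kd_di_p{i + 1}" for i in range(window_length - 1)
    ]


def encode_ncp(seq: RnaSequence) -> np.ndarray:
    """Chemical-property triplets (ring structure, functional group,
    hydrogen-bond strength) per residue; dimension 3λ."""
    return np.array(
        [v for nt in seq.residues for v in NCP_TABLE[nt]], dtype=float
    )


def ncp_feature_names(window_length: int) -> list[str]:
    return [
        f"ncp_p{i + 1}_{prop}"
        for i in range(window_length)
        for prop in ("ring", "func", "hbond")
    ]


# ---------------------------------------------------------------------------
# PseDNC


def _load_property_table() -> np.ndarray:
    """Raw (16, 3) property table in canonical dinucleotide order."""
    raw = {}
    text = (
        resources.files("pseusite")
        .joinpath("data/dinucleotide_properties.tsv")
        .read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("dinucleotide"):
            continue
        di, *vals = line.split("\t")
        raw[di] = [float(v) for v in vals]
    return np.array([raw[di] for di in DINUCLEOTIDES])


def _standardize(table: np.ndarray) -> np.ndarray:
    return (table - table.mean(axis=0)) / table.std(axis=0)


@dataclass
class PseDncConfig:
    """Configuration for pseudo dinucleotide composition.

    Parameters
    ----------
    lambda_pse:
        Number of sequence-order correlation tiers (counted rank);
        must satisfy lambda_pse < λ − 1.
    weight_w:
        Weight of the correlation factors relative to the dinucleotide
        frequencies, in (0, 1].
    property_table:
        (16, 3) array of free energy, stacking energy and hydrophilicity
        per dinucleotide in canonical order, standardized to zero mean and
        unit variance over the 16 dinucleotides. Defaults to the packaged
        published tables.
    """

    lambda_pse: int = 2
    weight_w: float = 0.1
    property_table: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lambda_pse < 0:
            raise EncoderError("lambda_pse must be non-negative")
        if not 0 < self.weight_w <= 1:
            raise EncoderError("weight_w must lie in (0, 1]")
        if self.property_table is None:
            self.property_table = _standardize(_load_property_table())
        else:
            self.property_table = _standardize(
                np.asarray(self.property_table, dtype=float)
            )
        if self.property_table.shape != (16, 3):
            raise EncoderError("property_table must be 16 x 3")


def encode_psednc(seq: RnaSequence, config: Optional[PseDncConfig] = None) -> np.ndarray:
    """Pseudo dinucleotide composition.

    First 16 components: d_k = f_k / (Σf + w·Σθ) with f_k the normalized
    dinucleotide frequencies. Last λ_pse components: d_{16+j} =
    w·θ_j / (Σf + w·Σθ), where θ_j is the mean over positions of the
    correlation Θ between dinucleotides j apart, and Θ is the mean squared
    difference of the three standardized physicochemical properties.
    All components are non-negative and sum to one.
    """
    if config is None:
        config = PseDncConfig()
    lam = seq.length
    if lam - 1 <= config.lambda_pse:
        raise EncoderError(
            f"lambda_pse={config.lambda_pse} requires window length "
            f"> {config.lambda_pse + 1}, got {lam}"
        )
    di_idx = np.array(
        [_DI_INDEX[seq.residues[i : i + 2]] for i in range(lam - 1)]
    )
    freqs = np.bincount(di_idx, minlength=16).astype(float)
    freqs /= freqs.sum()
    props = config.property_table[di_idx]  # (λ−1, 3)
    thetas = np.empty(config.lambda_pse)
    for j in range(1, config.lambda_pse + 1):
        diffs = props[:-j] - props[j:]
        thetas[j - 1] = np.mean(np.mean(diffs**2, axis=1))
    denom = 1.0 + config.weight_w * thetas.sum()
    return np.concatenate([freqs / denom, config.weight_w * thetas / denom])


def psednc_feature_names(lambda_pse: int) -> list[str]:
    return [f"psednc_{di}" for di in DINUCLEOTIDES] + [
        f"psednc_theta{j + 1}" for j in range(lambda_pse)
    ]


# ---------------------------------------------------------------------------
# PSKP


@dataclass
class PropensityTable:
    """Position-specific nucleotide propensities.

    mono[p, n] = freq(+)(nucleotide n at position p) − freq(−)(n at p);
    di analogously over dinucleotide start positions. Entries lie in
    [−1, 1]; identical positive and negative sets yield the zero table.
    """

    mono: np.ndarray  # (λ, 4)
    di: np.ndarray  # (λ−1, 16)
    window_length: int

    def __post_init__(self) -> None:
        self.mono = np.asarray(self.mono, dtype=float)
        self.di = np.asarray(self.di, dtype=float)
        lam = self.window_length
        if self.mono.shape != (lam, 4) or self.di.shape != (lam - 1, 16):
            raise EncoderError("propensity table shape inconsistent with λ")
        if np.abs(self.mono).max(initial=0) > 1 + 1e-12 or np.abs(
            self.di
        ).max(initial=0) > 1 + 1e-12:
            raise EncoderError("propensity entries must lie in [−1, 1]")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("position\tsymbol\tvalue\n")
            for p in range(self.window_length):
                for k, nt in enumerate(NUCLEOTIDES):
                    out.write(f"{p + 1}\t{nt}\t{self.mono[p, k]:.10g}\n")
            for p in range(self.window_length - 1):
                for k, di in enumerate(DINUCLEOTIDES):
                    out.write(f"{p + 1}\t{di}\t{self.di[p, k]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropensityTable":
        rows = []
        with open(path) as handle:
            next(handle)
            for line in handle:
                pos, symbol, value = line.split("\t")
                rows.append((int(pos), symbol, float(value)))
        lam = max(p for p, s, _ in rows if len(s) == 1)
        mono = np.zeros((lam, 4))
        di = np.zeros((lam - 1, 16))
        for pos, symbol, value in rows:
            if len(symbol) == 1:
                mono[pos - 1, _NT_INDEX[symbol]] = value
            else:
                di[pos - 1, _DI_INDEX[symbol]] = value
        return cls(mono, di, lam)


def _positional_frequencies(
    sequences: Sequence[RnaSequence], lam: int
) -> tuple[np.ndarray, np.ndarray]:
    mono = np.zeros((lam, 4))
    di = np.zeros((lam - 1, 16))
    for seq in sequences:
        for i, nt in enumerate(seq.residues):
            mono[i, _NT_INDEX[nt]] += 1
        for i in range(lam - 1):
            di[i, _DI_INDEX[seq.residues[i : i + 2]]] += 1
    return mono / len(sequences), di / len(sequences)


def fit_pskp(
    pos: Sequence[RnaSequence], neg: Sequence[RnaSequence]
) -> PropensityTable:
    """Fit the propensity table from positive vs negative training windows.

    Because the table is label-derived, it must be fitted on training
    folds only inside any cross-validation to avoid leakage.
    """
    if not pos or not neg:
        raise EncoderError("both training sets must be non-empty")
    lengths = {s.length for s in pos} | {s.length for s in neg}
    if len(lengths) != 1:
        raise EncoderError(f"heterogeneous window lengths: {sorted(lengths)}")
    lam = lengths.pop()
    mono_pos, di_pos = _positional_frequencies(pos, lam)
    mono_neg, di_neg = _positional_frequencies(neg, lam)
    return PropensityTable(mono_pos - mono_neg, di_pos - di_neg, lam)


def encode_pskp(seq: RnaSequence, table: PropensityTable) -> np.ndarray:
    """Look up per-position propensities for the sequence; 2λ−1 values."""
    if seq.length != table.window_length:
        raise EncoderError(
            f"{seq.seq_id}: length {seq.length} != table window "
            f"{table.window_length}"
        )
    lam = seq.length
    vec = np.empty(2 * lam - 1)
    for i, nt in enumerate(seq.residues):
        vec[i] = table.mono[i, _NT_INDEX[nt]]
    for i in range(lam - 1):
        vec[lam + i] = table.di[i, _DI_INDEX[seq.residues[i : i + 2]]]
    return vec


def pskp_feature_names(window_length: int) -> list[str]:
    return [f"pskp_mono_p{i + 1}" for i in range(window_length)] + [
        f"pskp_di_p{i + 1}" for i in range(window_length - 1)
    ]


# ---------------------------------------------------------------------------
# Dataset-level encoding


def encode_sequences(
    sequences: Sequence[RnaSequence],
    descriptor: str,
    pskp_table: Optional[PropensityTable] = None,
    psednc_config: Optional[PseDncConfig] = None,
) -> np.ndarray:
    """Stack one feature vector per sequence, preserving order."""
    descriptor = descriptor.upper()
    if descriptor not in DESCRIPTORS:
        raise EncoderError(f"unknown descriptor {descriptor!r}")
    if not sequences:
        raise EncoderError("no sequences to encode")
    if descriptor == "PSKP":
        if pskp_table is None:
            raise EncoderError("PSKP encoding requires a fitted PropensityTable")
        return np.stack([encode_pskp(s, pskp_table) for s in sequences])
    if descriptor == "PSEDNC":
        config = psednc_config or PseDncConfig()
        return np.stack([encode_psednc(s, config) for s in sequences])
    encoder = {
        "ONEHOT": encode_one_hot,
        "KMER": encode_kmer,
        "KD": encode_kd,
        "NCP": encode_ncp,
    }[descriptor]
    return np.stack([encoder(s) for s in sequences])


def feature_names(
    descriptor: str, window_length: int, lambda_pse: int = 2
) -> list[str]:
    descriptor = descriptor.upper()
    return {
        "ONEHOT": lambda: one_hot_feature_names(window_length),
        "KMER": kmer_feature_names,
        "KD": lambda: kd_feature_names(window_length),
        "PSEDNC": lambda: psednc_feature_names(lambda_pse),
        "PSKP": lambda: pskp_feature_names(window_length),
        "NCP": lambda: ncp_feature_names(window_length),
    }[descriptor]()


def encode_dataset(
    dataset: LabeledDataset,
    descriptor: str,
    pskp_table: Optional[PropensityTable] = None,
    psednc_config: Optional[PseDncConfig] = None,
) -> FeatureMatrix:
    """Encode every window of a labeled dataset with one descriptor.

    Row order follows dataset order; labels are carried through. PSKP
    requires an already-fitted table (fit it on training folds only).
    """
    descriptor = descriptor.upper()
    if len(dataset) == 0:
        raise EncoderError("empty dataset")
    values = encode_sequences(
        dataset.sequences, descriptor, pskp_table, psednc_config
    )
    lambda_pse = (psednc_config or PseDncConfig()).lambda_pse
    names = feature_names(descriptor, dataset.window_length, lambda_pse)
    return FeatureMatrix(values, names, descriptor, dataset.labels)
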