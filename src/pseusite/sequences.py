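"""RNA sequence containers and FASTA I/O.

The unit of classification is a fixed-length, U-centered window (21 or 31 nt
in the published benchmarks). This module reads FASTA, normalizes residues to
the 4-letter RNA alphabet (uppercase, T→U), and assembles labeled datasets of
positive (pseudouridine site) and negative (non-site) windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = "AUCG"

__all__ = [
    "RnaSequence",
    "LabeledDataset",
    "AlphabetError",
    "FastaFormatError",
    "DatasetError",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "validate_dataset",
]


class AlphabetError(ValueError):
    """A residue outside {A,C,G,U,T} (either case) was encountered."""


class FastaFormatError(ValueError):
    """The input file is not parseable FASTA."""


class DatasetError(ValueError):
    """Dataset-level invariant violated (lengths, center residue, labels)."""


def normalize_sequence(raw: str) -> str:
    """Normalize raw residue text to the RNA alphabet {A,U,C,G}.

    Uppercases, strips whitespace, and maps T→U (DNA-alphabet benchmark
    files are common). Ambiguity codes are rejected, not imputed, because
    every downstream encoder is defined only over the 4-letter alphabet.

    Raises
    ------
    AlphabetError
        Naming the offending character and its 1-based position.
    """
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    if not cleaned:
        raise AlphabetError("empty sequence after normalization")
    for pos, char in enumerate(cleaned, start=1):
        if char not in RNA_ALPHABET:
            raise AlphabetError(
                f"invalid residue {char!r} at position {pos}: "
                f"only A, C, G, U/T are accepted"
            )
    return cleaned


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over {A,U,C,G} with an identifier."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(RNA_ALPHABET)
        if bad or not self.residues:
            object.__setattr__(
                self, "residues", normalize_sequence(self.residues)
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def center_residue(self) -> str:
        """Residue at the center position (λ+1)/2, 1-based; λ must be odd."""
        if self.length % 2 == 0:
            raise DatasetError(
                f"{self.seq_id}: even length {self.length} has no center"
            )
        return self.residues[self.length // 2]


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read and normalize all records of a FASTA file, in file order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(RnaSequence(rec.id, normalize_sequence(str(rec.seq))))
        except AlphabetError as exc:
            raise AlphabetError(f"{path}: record {rec.id}: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Iterable[RnaSequence], path: str | Path) -> None:
    """Write sequences as single-line-per-record FASTA."""
    records = [
        SeqRecord(Seq(s.residues), id=s.seq_id, description="")
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a two-column (seq_id, label ∈ {0,1}) whitespace/tab table."""
    labels: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in {"0", "1"}:
                raise DatasetError(
                    f"{path}: line {lineno}: expected 'seq_id 0|1'"
                )
            labels[parts[0]] = int(parts[1])
    return labels


@dataclass
class LabeledDataset:
    """Equal-length U-centered windows with binary site labels.

    Label convention: 1 = pseudouridine site, 0 = non-site.
    """

    sequences: list[RnaSequence]
    labels: np.ndarray
    window_length: int = field(default=0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.window_length == 0 and self.sequences:
            self.window_length = self.sequences[0].length

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices)
        return LabeledDataset(
            [self.sequences[i] for i in idx],
            self.labels[idx],
            self.window_length,
        )

    @property
    def positives(self) -> list[RnaSequence]:
        return [s for s, l in zip(self.sequences, self.labels) if l == 1]

    @property
    def negatives(self) -> list[RnaSequence]:
        return [s for s, l in zip(self.sequences, self.labels) if l == 0]


def validate_dataset(
    pos: Sequence[RnaSequence],
    neg: Sequence[RnaSequence],
    window_length: int,
) -> LabeledDataset:
    """Merge positive and negative window sets into a validated dataset.

    Checks that every window has the stated (odd) length and a U at the
    center position (λ+1)/2 (1-based). Errors list every offending seq_id.
    """
    if not pos or not neg:
        raise DatasetError("both positive and negative sets must be non-empty")
    if window_length % 2 == 0 or window_length < 1:
        raise DatasetError(
            f"window_length must be odd and positive, got {window_length}"
        )
    sequences = list(pos) + list(neg)
    wrong_length = [s.seq_id for s in sequences if s.length != window_length]
    if wrong_length:
        raise DatasetError(
            f"sequences not of length {window_length}: {', '.join(wrong_length)}"
        )
    center = window_length // 2
    non_u = [s.seq_id for s in sequences if s.residues[center] != "U"]
    if non_u:
        raise DatasetError(
            f"sequences without U at center position {center + 1}: "
            f"{', '.join(non_u)}"
        )
    labels = np.concatenate(
        [np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)]
    )
    return LabeledDataset(sequences, labels, window_length)
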