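"""Sliding-window site identification for arbitrary-length RNA.

Fixed-window classifiers cannot score an RNA of indeterminate length
directly. The scanner slides the ensemble's training window (length λ)
along the input, emitting one candidate per U whose full window fits
inside the sequence. U residues closer than (λ−1)/2 to either end cannot
be windowed — the encoders are undefined over padding symbols — so they
are reported as skipped rather than silently dropped. All positions are
1-based, following site-annotation convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .ensemble import EnsemblePredictor, predict_ensemble
from .sequences import RnaSequence

__all__ = ["SiteCall", "scan_sequence", "ScanResult", "write_calls_tsv", "write_calls_bed"]


@dataclass(frozen=True)
class SiteCall:
    """One scored U-centered window of a longer input sequence."""

    seq_id: str
    position: int  # 1-based index of the center U in the input
    window: RnaSequence
    label: int
    votes: tuple[int, ...]
    decision_values: tuple[float, ...]


@dataclass
class ScanResult:
    """Ordered site calls plus the U positions that could not be windowed."""

    calls: list[SiteCall]
    skipped_positions: list[int]

    @property
    def positive_positions(self) -> list[int]:
        return [c.position for c in self.calls if c.label == 1]


def candidate_positions(residues: str, window_length: int) -> tuple[list[int], list[int]]:
    """1-based positions of U with a full window, and of skipped U."""
    flank = (window_length - 1) // 2
    eligible, skipped = [], []
    for i, nt in enumerate(residues, start=1):
        if nt != "U":
            continue
        if flank < i <= len(residues) - flank:
            eligible.append(i)
        else:
            skipped.append(i)
    return eligible, skipped


def scan_sequence(
    seq: RnaSequence, ensemble: EnsemblePredictor
) -> ScanResult:
    """Score every eligible U-centered window with the ensemble."""
    lam = ensemble.window_length
    if seq.length < lam:
        raise ValueError(
            f"{seq.seq_id}: length {seq.length} shorter than the minimum "
            f"scannable length {lam} (the ensemble's training window)"
        )
    flank = (lam - 1) // 2
    eligible, skipped = candidate_positions(seq.residues, lam)
    windows = [
        RnaSequence(
            f"{seq.seq_id}:{pos}", seq.residues[pos - flank - 1 : pos + flank]
        )
        for pos in eligible
    ]
    if not windows:
        return ScanResult([], skipped)
    labels, votes, decisions = predict_ensemble(ensemble, windows)
    calls = [
        SiteCall(
            seq.seq_id,
            pos,
            window,
            int(labels[i]),
            tuple(int(v) for v in votes[i]),
            tuple(float(d) for d in decisions[i]),
        )
        for i, (pos, window) in enumerate(zip(eligible, windows))
    ]
    return ScanResult(calls, skipped)


def write_calls_tsv(
    results: dict[str, ScanResult],
    descriptors: Sequence[str],
    path: str | Path,
    skipped_path: str | Path | None = None,
) -> None:
    with open(path, "w") as out:
        vote_cols = "\t".join(f"vote_{d}" for d in descriptors)
        dv_cols = "\t".join(f"decision_{d}" for d in descriptors)
        out.write(f"seq_id\tposition\tlabel\t{vote_cols}\t{dv_cols}\n")
        for result in results.values():
            for call in result.calls:
                votes = "\t".join(str(v) for v in call.votes)
                dvs = "\t".join(f"{d:.6g}" for d in call.decision_values)
                out.write(
                    f"{call.seq_id}\t{call.position}\t{call.label}\t"
                    f"{votes}\t{dvs}\n"
                )
    if skipped_path is not None:
        with open(skipped_path, "w") as out:
            out.write("seq_id\tposition\n")
            for seq_id, result in results.items():
                for pos in result.skipped_positions:
                    out.write(f"{seq_id}\t{pos}\n")


def write_calls_bed(results: dict[str, ScanResult], path: str | Path) -> None:
    """BED-like export (0-based half-open single-base intervals).

    Score = number of positive votes out of six; only positive calls are
    written, named Y (pseudouridine) by site-annotation convention.
    """
    with open(path, "w") as out:
        for result in results.values():
            for call in result.calls:
                if call.label != 1:
                    continue
                out.write(
                    f"{call.seq_id}\t{call.position - 1}\t{call.position}\t"
                    f"pseudouridine\t{sum(call.votes)}\n"
                )
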