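#!/usr/bin/env python
"""Full-scale benchmark runner for user-supplied datasets.

Trains the six-descriptor ensemble at the published search budget
(80 particles, 300 iterations, phase switch at 200, ten-fold CV fitness)
on a positive/negative FASTA pair of U-centered windows — for example
the downloadable pseudouridine benchmark sets — then reports ten-fold
cross-validated SN/SP/ACC/MCC for the ensemble and each base predictor.

This is a long computation (hours on one CPU at full scale); scale the
budget down with --particles/--iterations for trial runs.

Usage:
    python scripts/full_benchmark.py --pos positives.fasta \
        --neg negatives.fasta --out results/benchmark --seed 1
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from pseusite import (
    EnsembleConfig,
    cross_validate_ensemble,
    predictor_correlation,
    read_fasta,
    train_ensemble,
    validate_dataset,
)
from pseusite.bpso import BpsoConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pos", required=True, help="FASTA of site windows")
    parser.add_argument("--neg", required=True, help="FASTA of non-site windows")
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--particles", type=int, default=80)
    parser.add_argument("--iterations", type=int, default=300)
    parser.add_argument("--phase-switch", type=int, default=200)
    parser.add_argument("--folds", type=int, default=10)
    args = parser.parse_args()

    pos = read_fasta(args.pos)
    neg = read_fasta(args.neg)
    dataset = validate_dataset(pos, neg, pos[0].length)
    print(f"dataset: {len(dataset)} windows of length {dataset.window_length}")

    config = EnsembleConfig(
        bpso=BpsoConfig(
            n_particles=args.particles,
            n_iterations=args.iterations,
            phase_switch_iteration=min(args.phase_switch, args.iterations),
            cv_folds=args.folds,
        ),
        random_seed=args.seed,
    )
    ensemble, selections = train_ensemble(dataset, config)
    args.out.mkdir(parents=True, exist_ok=True)
    ensemble.save(args.out / "ensemble.joblib")
    for descriptor, selection in selections.items():
        selection.save(args.out / f"{descriptor.lower()}_selection.tsv")
        print(
            f"{descriptor}: fitness {selection.best_fitness:.4f}, "
            f"{selection.n_selected} features, "
            f"C={selection.C:g}, gamma={selection.gamma:g}"
        )

    ens_metrics, base_metrics, base_pred = cross_validate_ensemble(
        dataset, selections, k=args.folds, seed=args.seed
    )
    report = {
        "ensemble": vars(ens_metrics),
        "bases": {d: vars(m) for d, m in base_metrics.items()},
    }
    try:
        corr = predictor_correlation(base_pred)
        np.savetxt(
            args.out / "base_predictor_correlation.tsv", corr,
            delimiter="\t", fmt="%.4f",
        )
    except ValueError:
        pass
    (args.out / "metrics.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
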