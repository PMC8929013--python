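"""Parallel fusion of six per-descriptor predictors by majority voting.

Six base predictors — one per feature descriptor — vote with hard labels;
the label with more than three votes wins. A 3–3 tie is resolved by the
sign of the summed signed margins (positive if the sum is exactly zero):
deterministic and evidence-based rather than a coin flip. A serial-fusion
baseline (concatenate the six masked feature blocks, retrain one SVM) is
provided for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .bpso import (
    BpsoConfig,
    FoldData,
    HyperparamGrid,
    SelectionResult,
    make_folds,
    run_bpso,
)
from .encoders import DESCRIPTORS, PseDncConfig, encode_sequences, fit_pskp
from .predictor import (
    BasePredictor,
    descriptor_fold_data,
    predict_base,
    train_base_predictor,
)
from .sequences import LabeledDataset, RnaSequence

ENSEMBLE_SCHEMA_VERSION = "pseusite-ensemble-1"
N_VOTERS = 6

__all__ = [
    "EnsembleConfig",
    "EnsemblePredictor",
    "majority_vote",
    "train_ensemble",
    "predict_ensemble",
    "serial_fusion_baseline",
]


def majority_vote(
    votes: Sequence[int],
    decision_values: Sequence[float],
    tie_rule: str = "margin_sum",
) -> int:
    """Fuse six binary votes; >3 wins, 3–3 resolved by the tie rule."""
    if len(votes) != N_VOTERS or len(decision_values) != N_VOTERS:
        raise ValueError(f"expected exactly {N_VOTERS} votes")
    n_positive = int(sum(votes))
    if n_positive > N_VOTERS // 2:
        return 1
    if n_positive < N_VOTERS // 2:
        return 0
    if tie_rule == "margin_sum":
        return 1 if sum(decision_values) >= 0 else 0
    if tie_rule == "positive":
        return 1
    if tie_rule == "negative":
        return 0
    raise ValueError(f"unknown tie rule {tie_rule!r}")


@dataclass
class EnsembleConfig:
    """Settings for training the six-predictor ensemble.

    ``bpso`` is a template: each descriptor's search gets its own seed
    derived from ``random_seed`` so the six searches are independent but
    jointly reproducible from one master seed.
    """

    bpso: BpsoConfig = field(default_factory=BpsoConfig)
    descriptors: tuple[str, ...] = DESCRIPTORS
    psednc_config: Optional[PseDncConfig] = None
    tie_rule: str = "margin_sum"
    random_seed: int = 0

    def __post_init__(self) -> None:
        descriptors = tuple(d.upper() for d in self.descriptors)
        if len(descriptors) != N_VOTERS or len(set(descriptors)) != N_VOTERS:
            raise ValueError(
                f"exactly {N_VOTERS} pairwise-distinct descriptors required, "
                f"got {descriptors}"
            )
        unknown = set(descriptors) - set(DESCRIPTORS)
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")
        self.descriptors = descriptors


@dataclass
class EnsemblePredictor:
    """Six trained base predictors fused by majority vote."""

    base_predictors: list[BasePredictor]
    tie_rule: str = "margin_sum"
    schema_version: str = ENSEMBLE_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if len(self.base_predictors) != N_VOTERS:
            raise ValueError(f"exactly {N_VOTERS} base predictors required")
        descriptors = [p.descriptor for p in self.base_predictors]
        if len(set(descriptors)) != N_VOTERS:
            raise ValueError("descriptors must be pairwise distinct")
        lengths = {p.window_length for p in self.base_predictors}
        if len(lengths) != 1:
            raise ValueError("all base predictors must share window length")

    @property
    def window_length(self) -> int:
        return self.base_predictors[0].window_length

    @property
    def descriptors(self) -> list[str]:
        return [p.descriptor for p in self.base_predictors]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "EnsemblePredictor":
        obj = joblib.load(path)
        if (
            not isinstance(obj, cls)
            or obj.schema_version != ENSEMBLE_SCHEMA_VERSION
        ):
            raise ValueError(f"{path}: not a {ENSEMBLE_SCHEMA_VERSION} archive")
        return obj


def _descriptor_seed(master_seed: int, index: int) -> int:
    child = np.random.SeedSequence(master_seed).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % (2**31))


def train_ensemble(
    dataset: LabeledDataset,
    config: Optional[EnsembleConfig] = None,
) -> tuple[EnsemblePredictor, dict[str, SelectionResult]]:
    """Run BPSO selection and SVM training for all six descriptors.

    One stratified fold partition (from the master seed) is shared by all
    six searches so their fitness values are comparable. Returns the
    assembled ensemble and the per-descriptor selection results.
    """
    config = config or EnsembleConfig()
    splits = make_folds(
        dataset.labels, config.bpso.cv_folds, config.random_seed
    )
    predictors: list[BasePredictor] = []
    selections: dict[str, SelectionResult] = {}
    for index, descriptor in enumerate(config.descriptors):
        fold_data = descriptor_fold_data(
            dataset, descriptor, splits, config.psednc_config
        )
        bpso_config = BpsoConfig(
            n_particles=config.bpso.n_particles,
            n_iterations=config.bpso.n_iterations,
            phase_switch_iteration=config.bpso.phase_switch_iteration,
            v_max=config.bpso.v_max,
            inertia=config.bpso.inertia,
            c1=config.bpso.c1,
            c2=config.bpso.c2,
            cv_folds=config.bpso.cv_folds,
            random_seed=_descriptor_seed(config.random_seed, index),
            grid=config.bpso.grid,
            phase2_update=config.bpso.phase2_update,
        )
        selection = run_bpso(None, dataset.labels, bpso_config, fold_data)
        selections[descriptor] = selection
        predictors.append(
            train_base_predictor(
                dataset, descriptor, selection, config.psednc_config
            )
        )
    return EnsemblePredictor(predictors, config.tie_rule), selections


def predict_ensemble(
    ensemble: EnsemblePredictor, sequences: Sequence[RnaSequence]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Majority-vote labels plus the full per-descriptor vote breakdown.

    Returns ``(labels, votes, decision_values)`` with votes and decision
    values of shape (n_sequences, 6) in ensemble descriptor order.
    """
    n = len(sequences)
    votes = np.zeros((n, N_VOTERS), dtype=int)
    decisions = np.zeros((n, N_VOTERS), dtype=float)
    if n == 0:
        return np.array([], dtype=int), votes, decisions
    for j, predictor in enumerate(ensemble.base_predictors):
        votes[:, j], decisions[:, j] = predict_base(predictor, sequences)
    labels = np.array(
        [
            majority_vote(votes[i], decisions[i], ensemble.tie_rule)
            for i in range(n)
        ]
    )
    return labels, votes, decisions


def serial_fusion_baseline(
    dataset: LabeledDataset,
    selections: dict[str, SelectionResult],
    grid: Optional[HyperparamGrid] = None,
    cv_folds: int = 10,
    seed: int = 0,
    exponent_step: int = 1,
    psednc_config: Optional[PseDncConfig] = None,
) -> tuple[BasePredictor, float]:
    """Serial fusion: concatenate the six masked blocks, retrain one SVM.

    (C, γ) are chosen by grid search over the geometric grid via
    stratified cross-validation (``exponent_step`` thins the 32×32 grid
    for scaled-down runs). Returns the fused predictor and its CV
    accuracy for comparison against the parallel ensemble.
    """
    grid = grid or HyperparamGrid()
    psednc_config = psednc_config or PseDncConfig()
    splits = make_folds(dataset.labels, cv_folds, seed)
    rng = np.random.default_rng(seed)

    def block(descriptor: str, sequences, pskp_table=None) -> np.ndarray:
        X = encode_sequences(
            sequences,
            descriptor,
            pskp_table=pskp_table,
            psednc_config=psednc_config,
        )
        mask = selections[descriptor].feature_mask
        return X[:, mask]

    # Per-fold concatenated matrices; PSKP refitted per training fold.
    fold_blocks = []
    for train_idx, test_idx in splits:
        train = dataset.subset(train_idx)
        table = fit_pskp(train.positives, train.negatives)
        test_seqs = [dataset.sequences[i] for i in test_idx]
        X_tr = np.hstack(
            [
                block(d, train.sequences, table if d == "PSKP" else None)
                for d in selections
            ]
        )
        X_te = np.hstack(
            [
                block(d, test_seqs, table if d == "PSKP" else None)
                for d in selections
            ]
        )
        fold_blocks.append(
            (X_tr, dataset.labels[train_idx], X_te, dataset.labels[test_idx])
        )

    exponents = range(grid.exponent_min, grid.exponent_max + 1, exponent_step)
    best = (-np.inf, None, None)
    for ec in exponents:
        for eg in exponents:
            C, gamma = grid.base**ec, grid.base**eg
            accs = [
                np.mean(
                    SVC(C=C, gamma=gamma, kernel="rbf", cache_size=64)
                    .fit(X_tr, y_tr)
                    .predict(X_te)
                    == y_te
                )
                for X_tr, y_tr, X_te, y_te in fold_blocks
            ]
            acc = float(np.mean(accs))
            if acc > best[0]:
                best = (acc, C, gamma)
    cv_acc, C, gamma = best

    table = fit_pskp(dataset.positives, dataset.negatives)
    X_full = np.hstack(
        [
            block(d, dataset.sequences, table if d == "PSKP" else None)
            for d in selections
        ]
    )
    model = SVC(C=C, gamma=gamma, kernel="rbf")
    model.fit(X_full, dataset.labels)
    fused = BasePredictor(
        descriptor="SERIAL",
        feature_mask=np.ones(X_full.shape[1], dtype=bool),
        C=C,
        gamma=gamma,
        model=model,
        window_length=dataset.window_length,
        pskp_table=table,
        psednc_config=psednc_config,
    )
    return fused, cv_acc
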