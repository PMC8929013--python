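"""Evaluation: confusion counts, SN/SP/ACC/MCC, cross-validation harness,
incremental-feature-selection baseline, and predictor-diversity analysis.

Metric definitions (positive class = pseudouridine site):

    SN  = TP / (TP + FN)                      sensitivity (recall on sites)
    SP  = TN / (TN + FP)                      specificity
    ACC = (TP + TN) / (TP + TN + FP + FN)     overall accuracy
    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

MCC is defined as 0 whenever any factor of its denominator is zero
(standard degenerate-table convention). Cross-validated metrics are
pooled over the concatenated out-of-fold predictions rather than averaged
per fold, which is stable with small folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.svm import SVC

from .bpso import HyperparamGrid, SelectionResult, build_fold_data, make_folds
from .sequences import LabeledDataset, RnaSequence

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "confusion_counts",
    "compute_metrics",
    "kfold_cv",
    "cross_validate_ensemble",
    "ifs_baseline",
    "predictor_correlation",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class Metrics:
    SN: float
    SP: float
    ACC: float
    MCC: float


def confusion_counts(
    predicted: Sequence[int], truth: Sequence[int]
) -> ConfusionCounts:
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    return ConfusionCounts(
        TP=int(np.sum((predicted == 1) & (truth == 1))),
        TN=int(np.sum((predicted == 0) & (truth == 0))),
        FP=int(np.sum((predicted == 1) & (truth == 0))),
        FN=int(np.sum((predicted == 0) & (truth == 1))),
    )


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return Metrics(SN=sn, SP=sp, ACC=acc, MCC=mcc)


def kfold_cv(
    dataset: LabeledDataset,
    train_fn: Callable[[LabeledDataset], Callable[[list[RnaSequence]], np.ndarray]],
    k: int = 10,
    seed: int = 0,
) -> tuple[Metrics, list[Metrics]]:
    """Stratified k-fold CV of an arbitrary training procedure.

    ``train_fn`` receives a training-fold dataset and must return a
    function mapping sequences to predicted labels. Everything
    label-derived (PSKP fitting, optionally BPSO selection) must happen
    inside ``train_fn`` so each fold is leakage-free. Pooled metrics over
    concatenated out-of-fold predictions are returned along with a
    per-fold breakdown.
    """
    splits = make_folds(dataset.labels, k, seed)
    pooled_pred = np.empty(len(dataset), dtype=int)
    per_fold = []
    for train_idx, test_idx in splits:
        predict = train_fn(dataset.subset(train_idx))
        test_seqs = [dataset.sequences[i] for i in test_idx]
        fold_pred = np.asarray(predict(test_seqs), dtype=int)
        pooled_pred[test_idx] = fold_pred
        per_fold.append(
            compute_metrics(confusion_counts(fold_pred, dataset.labels[test_idx]))
        )
    pooled = compute_metrics(confusion_counts(pooled_pred, dataset.labels))
    return pooled, per_fold


def _grid_search_cv_accuracy(
    fold_data, grid: HyperparamGrid, exponent_step: int
) -> tuple[float, float, float]:
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
                for X_tr, y_tr, X_te, y_te in fold_data.folds
            ]
            acc = float(np.mean(accs))
            if acc > best[0]:
                best = (acc, C, gamma)
    return best


def ifs_baseline(
    X: np.ndarray,
    labels: np.ndarray,
    grid: Optional[HyperparamGrid] = None,
    cv_folds: int = 10,
    seed: int = 0,
    subset_sizes: Optional[Sequence[int]] = None,
    exponent_step: int = 4,
    ranking: str = "f_stat",
) -> tuple[SelectionResult, list[tuple[int, float]]]:
    """Incremental feature selection: the greedy comparator to BPSO.

    Features are ranked (default: one-way ANOVA F-statistic) and nested
    subsets of increasing size are each evaluated by grid-searched,
    stratified CV accuracy; the best subset wins. Returns a
    SelectionResult (so it is directly comparable to a BPSO run) and the
    (size, accuracy) curve.
    """
    grid = grid or HyperparamGrid()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if ranking == "f_stat":
        scores, _ = f_classif(X, labels)
        scores = np.nan_to_num(scores, nan=-np.inf)
    elif ranking == "abs_corr":
        centered = X - X.mean(axis=0)
        y_c = labels - labels.mean()
        denom = np.linalg.norm(centered, axis=0) * np.linalg.norm(y_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.abs(centered.T @ y_c) / denom
        scores = np.nan_to_num(scores, nan=-np.inf)
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    order = np.argsort(-scores)
    if subset_sizes is None:
        subset_sizes = range(1, X.shape[1] + 1)
    splits = make_folds(labels, cv_folds, seed)
    curve = []
    best = (-np.inf, None, None, None)
    for size in subset_sizes:
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[order[:size]] = True
        fold_data = build_fold_data(X[:, mask], labels, splits)
        acc, C, gamma = _grid_search_cv_accuracy(fold_data, grid, exponent_step)
        curve.append((size, acc))
        if acc > best[0]:
            best = (acc, mask, C, gamma)
    acc, mask, C, gamma = best
    result = SelectionResult(mask, C, gamma, acc, np.array([a for _, a in curve]))
    return result, curve


def cross_validate_ensemble(
    dataset: LabeledDataset,
    selections: dict,
    psednc_config=None,
    tie_rule: str = "margin_sum",
    k: int = 10,
    seed: int = 0,
) -> tuple[Metrics, dict[str, Metrics], np.ndarray]:
    """Stratified k-fold CV of the majority-vote ensemble and its bases.

    The six BPSO selections (masks and hyperparameters) are held fixed;
    inside each training fold the six SVMs — and the label-derived PSKP
    table — are re-fitted from scratch, then the out-of-fold windows are
    scored. Returns pooled ensemble metrics, pooled per-descriptor base
    metrics, and the matrix of pooled per-base predictions (one row per
    descriptor, dataset order) for diversity analysis.
    """
    from .ensemble import majority_vote
    from .predictor import predict_base, train_base_predictor

    descriptors = list(selections)
    splits = make_folds(dataset.labels, k, seed)
    n = len(dataset)
    base_pred = np.zeros((len(descriptors), n), dtype=int)
    ens_pred = np.zeros(n, dtype=int)
    for train_idx, test_idx in splits:
        train = dataset.subset(train_idx)
        test_seqs = [dataset.sequences[i] for i in test_idx]
        votes = np.zeros((len(test_idx), len(descriptors)), dtype=int)
        margins = np.zeros((len(test_idx), len(descriptors)))
        for j, descriptor in enumerate(descriptors):
            base = train_base_predictor(
                train, descriptor, selections[descriptor], psednc_config
            )
            votes[:, j], margins[:, j] = predict_base(base, test_seqs)
        base_pred[:, test_idx] = votes.T
        ens_pred[test_idx] = [
            majority_vote(votes[i], margins[i], tie_rule)
            for i in range(len(test_idx))
        ]
    ensemble_metrics = compute_metrics(
        confusion_counts(ens_pred, dataset.labels)
    )
    base_metrics = {
        d: compute_metrics(confusion_counts(base_pred[j], dataset.labels))
        for j, d in enumerate(descriptors)
    }
    return ensemble_metrics, base_metrics, base_pred


def predictor_correlation(predictions: Sequence[Sequence[int]]) -> np.ndarray:
    """Pairwise Pearson correlation of per-predictor prediction vectors.

    Low off-diagonal correlation indicates heterogeneous base predictors,
    the property that makes majority voting effective. A constant
    prediction vector has undefined correlation and is rejected.
    """
    arr = np.asarray(predictions, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array of prediction vectors")
    stds = arr.std(axis=1)
    constant = np.where(stds == 0)[0]
    if constant.size:
        raise ValueError(
            f"constant prediction vector(s) at index {constant.tolist()}: "
            "Pearson correlation undefined"
        )
    return np.corrcoef(arr)
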