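"""Per-descriptor RBF-SVM base predictors.

One base predictor per feature descriptor: the descriptor's BPSO-selected
feature mask, the decoded (C, γ) pair, and an RBF-kernel SVM fitted on the
masked features of the full training set. Fitted encoding artifacts (the
PSKP propensity table, the PseDNC configuration) travel inside the
predictor so that prediction-time encoding is self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .bpso import FoldData, SelectionResult, build_fold_data
from .encoders import (
    PropensityTable,
    PseDncConfig,
    descriptor_dimension,
    encode_sequences,
    fit_pskp,
)
from .sequences import LabeledDataset, RnaSequence

SCHEMA_VERSION = "pseusite-base-1"

__all__ = [
    "BasePredictor",
    "descriptor_fold_data",
    "train_base_predictor",
    "predict_base",
]


def descriptor_fold_data(
    dataset: LabeledDataset,
    descriptor: str,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    psednc_config: Optional[PseDncConfig] = None,
) -> FoldData:
    """Per-fold design matrices for one descriptor.

    For PSKP the propensity table is label-derived, so it is re-fitted on
    each training fold and applied to both fold halves — the encoded
    matrix differs per fold and never sees test-fold labels. All other
    descriptors are label-free and are encoded once.
    """
    descriptor = descriptor.upper()
    if descriptor != "PSKP":
        X = encode_sequences(
            dataset.sequences, descriptor, psednc_config=psednc_config
        )
        return build_fold_data(X, dataset.labels, splits)
    folds = []
    labels = dataset.labels
    for train_idx, test_idx in splits:
        train = dataset.subset(train_idx)
        table = fit_pskp(train.positives, train.negatives)
        X_tr = encode_sequences(train.sequences, "PSKP", pskp_table=table)
        test_seqs = [dataset.sequences[i] for i in test_idx]
        X_te = encode_sequences(test_seqs, "PSKP", pskp_table=table)
        folds.append((X_tr, labels[train_idx], X_te, labels[test_idx]))
    return FoldData(folds)


@dataclass
class BasePredictor:
    """A trained per-descriptor classifier (label 1 = pseudouridine)."""

    descriptor: str
    feature_mask: np.ndarray
    C: float
    gamma: float
    model: SVC
    window_length: int
    pskp_table: Optional[PropensityTable] = None
    psednc_config: Optional[PseDncConfig] = None
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.feature_mask = np.asarray(self.feature_mask, dtype=bool)

    def encode(self, sequences: Sequence[RnaSequence]) -> np.ndarray:
        for seq in sequences:
            if seq.length != self.window_length:
                raise ValueError(
                    f"{seq.seq_id}: length {seq.length} != training window "
                    f"{self.window_length}"
                )
        return encode_sequences(
            sequences,
            self.descriptor,
            pskp_table=self.pskp_table,
            psednc_config=self.psednc_config,
        )

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "BasePredictor":
        obj = joblib.load(path)
        if not isinstance(obj, cls) or obj.schema_version != SCHEMA_VERSION:
            raise ValueError(f"{path}: not a {SCHEMA_VERSION} archive")
        return obj


def train_base_predictor(
    dataset: LabeledDataset,
    descriptor: str,
    selection: SelectionResult,
    psednc_config: Optional[PseDncConfig] = None,
) -> BasePredictor:
    """Fit the descriptor's SVM on the full training set.

    The selection must have been produced for the same descriptor and
    window length: its mask length is checked against the descriptor's
    dimensionality contract.
    """
    descriptor = descriptor.upper()
    psednc_config = psednc_config or PseDncConfig()
    expected = descriptor_dimension(
        descriptor, dataset.window_length, psednc_config.lambda_pse
    )
    if len(selection.feature_mask) != expected:
        raise ValueError(
            f"mask length {len(selection.feature_mask)} != {descriptor} "
            f"dimension {expected} at window length {dataset.window_length}"
        )
    pskp_table = None
    if descriptor == "PSKP":
        pskp_table = fit_pskp(dataset.positives, dataset.negatives)
    X = encode_sequences(
        dataset.sequences,
        descriptor,
        pskp_table=pskp_table,
        psednc_config=psednc_config,
    )
    model = SVC(C=selection.C, gamma=selection.gamma, kernel="rbf")
    model.fit(X[:, selection.feature_mask], dataset.labels)
    return BasePredictor(
        descriptor=descriptor,
        feature_mask=selection.feature_mask,
        C=selection.C,
        gamma=selection.gamma,
        model=model,
        window_length=dataset.window_length,
        pskp_table=pskp_table,
        psednc_config=psednc_config,
    )


def predict_base(
    predictor: BasePredictor, sequences: Sequence[RnaSequence]
) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and signed margins for fixed-length windows.

    Label 1 iff the decision value (signed distance to the separating
    surface) is positive; margins are retained for ensemble tie-breaking.
    """
    if not sequences:
        return np.array([], dtype=int), np.array([], dtype=float)
    X = predictor.encode(sequences)[:, predictor.feature_mask]
    decision = predictor.model.decision_function(X)
    return (decision > 0).astype(int), decision
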