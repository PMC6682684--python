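"""Single-trial target/non-target SWLDA classification of speller epochs.

Each 800 ms epoch is decimated by averaging non-overlapping blocks of 24
samples (409 samples at 512 Hz -> 17 block means per channel, a 32 x 17
feature vector) and flattened. Stepwise linear discriminant analysis — least
squares on +-1 labels with forward/backward partial-F feature selection
capped at 60 features — yields a linear score, and the area under the ROC
curve of the scores is the per-subject offline performance: with a 1:5
target/non-target imbalance, accuracy would be uninformative. The reported
value is the mean AUC over stratified 10-fold cross-validation, with
features re-selected on every training fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .preprocess import EpochSet
from .stepwise import StepwiseResult, stepwise_select

__all__ = [
    "SwldaModel",
    "decimate_epoch",
    "build_design",
    "swlda_fit",
    "swlda_score",
    "auc",
    "crossval_auc",
]


@dataclass(frozen=True)
class SwldaModel:
    """Fitted SWLDA discriminant: selected features and their weights."""

    selected_features: tuple[int, ...]
    weights: np.ndarray
    intercept: float
    p_enter: float
    p_remove: float
    max_features: int

    @property
    def is_empty(self) -> bool:
        return len(self.selected_features) == 0


def decimate_epoch(epoch: np.ndarray, block: int = 24) -> np.ndarray:
    """Average non-overlapping blocks of ``block`` samples per channel.

    A trailing remainder shorter than one block is discarded (409 samples ->
    17 blocks with one sample dropped).
    """
    epoch = np.asarray(epoch, dtype=float)
    n = epoch.shape[-1]
    if n < block:
        raise ValueError(f"need >= {block} samples, got {n}")
    nb = n // block
    trimmed = epoch[..., : nb * block]
    return trimmed.reshape(*epoch.shape[:-1], nb, block).mean(axis=-1)


def build_design(epochs: EpochSet, block: int = 24,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Decimate and flatten retained epochs into (X, y01).

    Rows are epochs, columns channel-major decimated time points
    (n_channels x n_blocks); y01 is 1 for targets, 0 for non-targets.
    """
    kept = epochs.retained()
    X = decimate_epoch(kept.data, block=block).reshape(kept.n_epochs, -1)
    y = kept.is_target.astype(int)
    return X, y


def swlda_fit(X: np.ndarray, y: np.ndarray, max_features: int = 60,
              p_enter: float = 0.10, p_remove: float = 0.15) -> SwldaModel:
    """Fit the stepwise discriminant on a design matrix with 0/1 labels."""
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    target = y == classes.max()
    coded = np.where(target, 1.0, -1.0)
    res: StepwiseResult = stepwise_select(X, coded, p_enter=p_enter,
                                          p_remove=p_remove,
                                          max_features=max_features)
    return SwldaModel(selected_features=res.selected, weights=res.coef,
                      intercept=res.intercept, p_enter=p_enter,
                      p_remove=p_remove, max_features=max_features)


def swlda_score(model: SwldaModel, X: np.ndarray) -> np.ndarray:
    """Linear read-out: intercept + sum of weight x feature.

    An empty model returns identical scores for every row (chance-level
    ranking).
    """
    X = np.asarray(X, dtype=float)
    if model.is_empty:
        return np.full(X.shape[0], model.intercept)
    sel = list(model.selected_features)
    if max(sel) >= X.shape[1]:
        raise ValueError("feature index exceeds design width")
    return model.intercept + X[:, sel] @ model.weights


def auc(scores, labels) -> float:
    """Area under the ROC curve, rank (Mann-Whitney) formulation.

    The probability that a randomly drawn target outscores a randomly drawn
    non-target, ties counted one half.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def crossval_auc(epochs: EpochSet, k: int = 10, seed: int = 0,
                 max_features: int = 60, p_enter: float = 0.10,
                 p_remove: float = 0.15, block: int = 24,
                 ) -> tuple[float, np.ndarray]:
    """Stratified k-fold cross-validated SWLDA AUC of an epoch set.

    Epochs are shuffled once with ``seed`` and split into k stratified folds;
    per fold the discriminant (including its feature selection) is refit on
    the training epochs and scored on the held-out ones. Returns
    (mean AUC, per-fold AUCs). A degenerate fold whose model is empty
    contributes 0.5.
    """
    X, y = build_design(epochs, block=block)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs = []
    for train, test in skf.split(X, y):
        if np.unique(y[test]).size < 2:
            raise ValueError("fold without both classes")
        model = swlda_fit(X[train], y[train], max_features=max_features,
                          p_enter=p_enter, p_remove=p_remove)
        if model.is_empty:
            fold_aucs.append(0.5)
            continue
        fold_aucs.append(auc(swlda_score(model, X[test]), y[test]))
    fold_aucs = np.asarray(fold_aucs)
    return float(fold_aucs.mean()), fold_aucs
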