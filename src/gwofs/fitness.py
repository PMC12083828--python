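"""Sigmoid binarization and the KNN-wrapper fitness function.

A wolf's continuous position in ``[0,1]^D`` is mapped to a feature mask by a
steep logistic transfer function and a per-dimension uniform draw; the mask
is scored by the mean fold error of a K-nearest-neighbour classifier under
stratified k-fold cross-validation (lower is better, 0 = perfect).

The KNN scoring is a vectorized Euclidean distance-matrix implementation
with fully deterministic tie-breaking: neighbour-distance ties and vote
ties are both resolved in favour of the lowest class index.  Stratified
fold assignment comes from scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import Dataset, FeatureMask

#: Transfer function sigma(x) = 1 / (1 + exp(-steepness * (x - center))).
SIGMOID_STEEPNESS = 10.0
SIGMOID_CENTER = 0.5


def sigmoid_transfer(alpha):
    """Logistic transfer sigma(alpha) = 1 / (1 + e^{-10 (alpha - 0.5)}).

    Strictly increasing, maps the reals into (0, 1) with sigma(0.5) = 0.5.
    Accepts scalars or arrays; rejects non-finite input.
    """
    a = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("sigmoid_transfer requires finite input")
    out = 1.0 / (1.0 + np.exp(-SIGMOID_STEEPNESS * (a - SIGMOID_CENTER)))
    return out if out.ndim else float(out)


def binarize(position: np.ndarray, rng: np.random.Generator) -> FeatureMask:
    """Stochastic threshold: bit_j = 1 iff sigma(position_j) > r_j, r_j ~ U(0,1).

    An all-zero mask is repaired by setting one uniformly random bit, since
    the classifier needs at least one feature column.
    """
    position = np.asarray(position, dtype=float)
    bits = sigmoid_transfer(position) > rng.random(position.shape[0])
    if not bits.any():
        bits[rng.integers(position.shape[0])] = True
    return FeatureMask(bits)


@dataclass(frozen=True)
class FitnessResult:
    """Per-fold error rates and their mean (the fitness)."""

    fold_errors: np.ndarray
    fitness: float
    predictions: tuple | None = None  # per-fold (test_idx, y_pred) when requested


def make_folds(dataset: Dataset, folds: int, fold_seed: int):
    """Precompute stratified fold index pairs, shared by all evaluations in a run.

    The effective fold count is ``min(folds, L, smallest class count)`` so
    stratification stays valid on tiny datasets.
    """
    eff = min(folds, dataset.n_samples, int(dataset.class_counts.min()))
    eff = max(eff, 2)
    skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=int(fold_seed) % (2**32))
    return [
        (tr.astype(np.intp), te.astype(np.intp))
        for tr, te in skf.split(dataset.features, dataset.labels)
    ]


def _knn_predict(d2_block: np.ndarray, y_train: np.ndarray, k: int, n_classes: int) -> np.ndarray:
    """Predict test labels from a (n_test, n_train) squared-distance block.

    Assumes the training columns are pre-sorted by class label so that a
    stable argsort resolves distance ties in favour of the lowest class.
    Vote ties resolve to the lowest class via argmax on the count table.
    """
    k = min(k, d2_block.shape[1])
    order = np.argsort(d2_block, axis=1, kind="stable")[:, :k]
    neigh = y_train[order]  # (n_test, k)
    counts = np.zeros((d2_block.shape[0], n_classes), dtype=np.intp)
    rows = np.repeat(np.arange(d2_block.shape[0]), k)
    np.add.at(counts, (rows, neigh.ravel()), 1)
    return counts.argmax(axis=1)


def cv_error(
    dataset: Dataset,
    mask: FeatureMask,
    folds: int = 10,
    knn_k: int = 5,
    fold_seed: int = 0,
    fold_plan=None,
    scale: bool = False,
    return_predictions: bool = False,
) -> FitnessResult:
    """Mean KNN classification error rate over stratified CV folds.

    For each fold the classifier is trained on the remaining folds using the
    selected feature columns only; error_i = misclassified / total in the
    fold, and fitness = sum(error_i) / folds.  Deterministic given
    ``fold_seed`` (or an explicit precomputed ``fold_plan``).
    """
    if mask.size < 1:
        raise ValueError("mask selects no features")
    if fold_plan is None:
        fold_plan = make_folds(dataset, folds, fold_seed)
    Xm = dataset.features[:, mask.bits]
    y = dataset.labels
    n_classes = dataset.n_classes
    errors = np.empty(len(fold_plan))
    preds = [] if return_predictions else None
    for f, (tr, te) in enumerate(fold_plan):
        # sort training rows by class so stable distance sorting breaks ties
        # in favour of the lowest class index
        tr = tr[np.argsort(y[tr], kind="stable")]
        Xtr, Xte = Xm[tr], Xm[te]
        if scale:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        d2 = (
            np.sum(Xte**2, axis=1)[:, None]
            + np.sum(Xtr**2, axis=1)[None, :]
            - 2.0 * (Xte @ Xtr.T)
        )
        y_pred = _knn_predict(d2, y[tr], knn_k, n_classes)
        errors[f] = np.mean(y_pred != y[te])
        if return_predictions:
            preds.append((te.copy(), y_pred))
    return FitnessResult(
        fold_errors=errors,
        fitness=float(errors.mean()),
        predictions=tuple(preds) if return_predictions else None,
    )
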