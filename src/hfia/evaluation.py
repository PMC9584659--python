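"""Wrapper fitness: KNN cross-validation error of a feature subset.

A candidate subset is scored by the aggregated fitness

    fitness = omega * E_r + (1 - omega) * p / q ,

where ``E_r`` is the cross-validated misclassification rate of a
k-nearest-neighbour classifier restricted to the subset, ``p`` the subset
size, ``q`` the size of the evaluated feature space and ``omega`` the
accuracy weight.  Lower is better; affinity, where the search ranks by
it, is the negation.

Determinism contract of the evaluator: stratified folds are derived from
the config seed over a canonical sample order (sorted sample ids when
present); neighbour ties resolve by the earlier training sample; vote
ties resolve to the smallest class label under a fixed total order.  If
any class is smaller than the fold count, the evaluator falls back to
leave-one-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_io import LabeledDataset

__all__ = [
    "FitnessConfig",
    "FitnessResult",
    "FitnessCache",
    "knn_cv_error",
    "fitness",
    "evaluate_mask",
    "evaluate_antibody",
]


@dataclass(frozen=True)
class FitnessConfig:
    """Evaluator parameters.

    omega
        Weight of the error-rate term, in (0, 1).  Default 0.99: almost
        all weight on accuracy, with a small pressure toward smaller
        subsets that breaks ties between equally accurate subsets.
    knn_k
        Neighbour count; capped at the training-fold size.
    cv_folds
        Stratified fold count; leave-one-out replaces it when some class
        is smaller than ``cv_folds``.
    standardize
        Z-score columns using training-fold statistics only.  Off by
        default: expression matrices are conventionally evaluated raw.
    """

    omega: float = 0.99
    knn_k: int = 5
    cv_folds: int = 5
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.omega < 1.0:
            raise ValueError(f"omega must be in (0, 1), got {self.omega}")
        if self.knn_k < 1:
            raise ValueError(f"knn_k must be >= 1, got {self.knn_k}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")


@dataclass(frozen=True)
class FitnessResult:
    error_rate: float
    p: int
    q: int
    fitness: float


class FitnessCache:
    """Mask -> error-rate store; identical masks are evaluated once."""

    def __init__(self) -> None:
        self._store: dict[bytes, float] = {}
        self.n_evaluations = 0  # classifier evaluations actually run

    def error_rate(self, mask: np.ndarray, compute) -> float:
        key = np.packbits(mask.astype(np.uint8)).tobytes()
        if key not in self._store:
            self._store[key] = compute()
            self.n_evaluations += 1
        return self._store[key]


def _predict_knn(train_X: np.ndarray, train_y: np.ndarray,
                 test_X: np.ndarray, k: int) -> np.ndarray:
    """Majority-vote KNN with deterministic tie handling.

    Neighbour ties at the k-th distance keep the earlier training sample
    (stable argsort); vote ties return the smallest encoded label.
    """
    d2 = (
        (test_X ** 2).sum(axis=1)[:, None]
        - 2.0 * test_X @ train_X.T
        + (train_X ** 2).sum(axis=1)[None, :]
    )
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    votes = train_y[order]
    n_classes = int(train_y.max()) + 1
    counts = np.zeros((test_X.shape[0], n_classes), dtype=np.intp)
    for j in range(k):
        np.add.at(counts, (np.arange(test_X.shape[0]), votes[:, j]), 1)
    return counts.argmax(axis=1)  # argmax picks the smallest label on ties


def _fold_indices(y: np.ndarray, cv_folds: int, seed: int) -> list[np.ndarray]:
    """Stratified test-fold index lists, or singletons for the LOOCV fallback."""
    class_counts = np.bincount(y)
    if class_counts[class_counts > 0].min() < cv_folds:
        return [np.array([i]) for i in range(len(y))]
    splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                               random_state=seed % (2**31 - 1))
    return [test for _, test in splitter.split(np.zeros_like(y), y)]


def knn_cv_error(dataset: LabeledDataset, feature_mask: np.ndarray,
                 config: FitnessConfig) -> float:
    """Mean misclassification fraction of KNN over cross-validation folds.

    Fold assignment is derived from ``config.seed`` over the canonical
    sample order (sorted sample ids when present), so the estimate is
    invariant to permuting the rows of the dataset.
    """
    mask = np.asarray(feature_mask, dtype=bool)
    if not mask.any():
        raise ValueError("feature mask selects no features")
    X = dataset.matrix[:, mask]
    y = dataset.encoded_labels()

    if dataset.sample_ids is not None:
        canonical = np.argsort(np.asarray(dataset.sample_ids, dtype=object),
                               kind="stable")
        X, y = X[canonical], y[canonical]

    n_errors = 0
    for test_idx in _fold_indices(y, config.cv_folds, config.seed):
        train_sel = np.ones(len(y), dtype=bool)
        train_sel[test_idx] = False
        train_X, train_y = X[train_sel], y[train_sel]
        test_X = X[test_idx]
        if config.standardize:
            mu = train_X.mean(axis=0)
            sd = train_X.std(axis=0)
            sd[sd == 0.0] = 1.0
            train_X = (train_X - mu) / sd
            test_X = (test_X - mu) / sd
        k = min(config.knn_k, len(train_y))
        pred = _predict_knn(train_X, train_y, test_X, k)
        n_errors += int((pred != y[test_idx]).sum())
    return n_errors / len(y)


def fitness(error_rate: float, p: int, q: int, omega: float) -> float:
    """Aggregate subset quality; lower is better, affinity is its negation."""
    if q <= 0:
        raise ValueError("q must be positive")
    return omega * error_rate + (1.0 - omega) * (p / q)


def evaluate_mask(mask: np.ndarray, dataset: LabeledDataset,
                  config: FitnessConfig,
                  cache: FitnessCache | None = None) -> FitnessResult:
    """Score one binary feature mask over the evaluated space."""
    mask = np.asarray(mask, dtype=bool)
    q = dataset.n_features
    p = int(mask.sum())
    if cache is None:
        err = knn_cv_error(dataset, mask, config)
    else:
        err = cache.error_rate(mask, lambda: knn_cv_error(dataset, mask, config))
    return FitnessResult(error_rate=err, p=p, q=q,
                         fitness=fitness(err, p, q, config.omega))


def evaluate_antibody(antibody, dataset: LabeledDataset, config: FitnessConfig,
                      cache: FitnessCache | None = None) -> FitnessResult:
    """Score an antibody (any object with a binary ``code`` vector)."""
    return evaluate_mask(antibody.code, dataset, config, cache)
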