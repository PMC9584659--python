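"""Stage-1 filter: Fisher-score ranking of features.

The Fisher score of feature *i* is the ratio of the between-class
dispersion of its class means to the class-size-weighted sum of its
within-class variances,

    F_i = sum_k n_k (u_k^i - u^i)^2  /  sum_k n_k (sigma_k^i)^2 ,

with n_k the size of class k, u_k^i the class mean, u^i the overall mean
and (sigma_k^i)^2 the *population* within-class variance (divide by n_k;
the weighting by n_k makes the biased form the one that stays defined for
singleton classes).  Degenerate denominators are floored at EPS so scores
stay finite and totally ordered; a constant feature (0/0) scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import LabeledDataset

__all__ = ["EPS", "FisherScores", "FilteredDataset", "fisher_scores", "select_top_k"]

#: Floor applied to zero within-class variance sums.
EPS = 1e-12


@dataclass(frozen=True)
class FisherScores:
    """Per-feature Fisher statistics with their per-class moments."""

    scores: np.ndarray          # (q,) finite, >= 0
    class_counts: np.ndarray    # (c,) n_k, summing to n
    class_means: np.ndarray     # (c, q) u_k^i
    overall_means: np.ndarray   # (q,) u^i
    class_variances: np.ndarray  # (c, q) population (sigma_k^i)^2
    n_classes: int


@dataclass(frozen=True)
class FilteredDataset:
    """A dataset restricted to the top-scoring candidate features.

    ``original_indices[j]`` maps filtered column ``j`` back to the column
    of the source dataset; ``fisher_scores`` is non-increasing.
    """

    dataset: LabeledDataset
    original_indices: np.ndarray
    fisher_scores: np.ndarray

    @property
    def m(self) -> int:
        return len(self.original_indices)


def fisher_scores(dataset: LabeledDataset) -> FisherScores:
    """Compute the Fisher score of every feature.

    The 0/0 case (a feature constant everywhere) returns 0; a feature with
    zero within-class variance but distinct class means hits the EPS floor
    and ranks above every finite-variance feature.
    """
    X = dataset.matrix
    if X.size == 0:
        raise ValueError("empty dataset")
    y = dataset.encoded_labels()
    c = dataset.n_classes

    counts = np.bincount(y, minlength=c).astype(np.intp)
    means = np.empty((c, X.shape[1]))
    variances = np.empty((c, X.shape[1]))
    for k in range(c):
        block = X[y == k]
        means[k] = block.mean(axis=0)
        variances[k] = block.var(axis=0)  # population variance (ddof=0)
    overall = X.mean(axis=0)

    numerator = (counts[:, None] * (means - overall) ** 2).sum(axis=0)
    denominator = (counts[:, None] * variances).sum(axis=0)
    scores = np.where(numerator == 0.0, 0.0,
                      numerator / np.maximum(denominator, EPS))
    return FisherScores(
        scores=scores,
        class_counts=counts,
        class_means=means,
        overall_means=overall,
        class_variances=variances,
        n_classes=c,
    )


def rank_features(scores: FisherScores) -> np.ndarray:
    """Feature indices by non-increasing score, ties by ascending index."""
    # stable mergesort on -score keeps the ascending-index tie order
    return np.argsort(-scores.scores, kind="stable")


def select_top_k(scores: FisherScores, dataset: LabeledDataset,
                 fisher_k: int) -> FilteredDataset:
    """Retain the ``min(fisher_k, q)`` highest-scoring features.

    With fewer features than ``fisher_k`` the filter is a pass-through
    (still re-ordered by score).  Tie-break at the cut rank: ascending
    original index, for determinism.
    """
    if fisher_k < 1:
        raise ValueError(f"fisher_k must be >= 1, got {fisher_k}")
    order = rank_features(scores)
    m = min(fisher_k, dataset.n_features)
    keep = order[:m]
    return FilteredDataset(
        dataset=dataset.restrict_features(keep),
        original_indices=keep.astype(np.intp),
        fisher_scores=scores.scores[keep],
    )
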