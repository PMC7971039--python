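"""Majority-class cleaning for imbalanced binary datasets.

The neighborhood cleaning rule (NCL) removes two kinds of majority-class
samples: A1, those flagged noisy by Wilson's edited nearest neighbor rule
(label disagrees with the majority vote of their k nearest neighbors); and
A2, majority samples that sit among the k nearest neighbors of a minority
sample whose own neighborhood vote misclassifies it. Minority samples are
never removed. A seeded random undersampler is provided as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class NCLParams:
    k_neighbors: int = 3
    metric: str = "euclidean"
    scale_features: bool = True

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError(f"k_neighbors must be >= 1, got {self.k_neighbors}")


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _scaled(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return (X - mean) / std


def _knn_indices(X: np.ndarray, k: int, metric: str) -> np.ndarray:
    """Indices of the k nearest neighbors of each sample, self excluded.

    Brute-force pairwise distances; ties broken by lower sample index so the
    result is fully deterministic.
    """
    from sklearn.metrics import pairwise_distances

    dist = pairwise_distances(X, metric=metric)
    n = len(X)
    np.fill_diagonal(dist, np.inf)  # exclude self
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), dist), axis=1)
    return order[:, :k]


def enn_misclassified(X, y, k: int = 3, metric: str = "euclidean", scale: bool = True) -> np.ndarray:
    """Boolean mask: True where a sample's label loses the vote of its k
    nearest neighbors (self excluded)."""
    X = _as_array(X)
    y = np.asarray(y)
    n = len(X)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if scale:
        X = _scaled(X)
    neighbors = _knn_indices(X, k, metric)
    votes = (y[neighbors] == 1).sum(axis=1)
    predicted = np.where(votes * 2 > k, 1, np.where(votes * 2 < k, 0, y))
    return predicted != y


def ncl_resample(X, y, params: NCLParams | None = None):
    """Neighborhood cleaning: drop noisy majority samples (A1 union A2).

    Returns (X', y', removed_indices). Deterministic; minority rows pass
    through untouched and sample order is preserved.
    """
    params = params or NCLParams()
    is_frame = isinstance(X, pd.DataFrame)
    Xa = _as_array(X)
    y = np.asarray(y)
    classes, counts = np.unique(y), np.bincount(np.searchsorted(np.unique(y), y))
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]

    k = params.k_neighbors
    Xs = _scaled(Xa) if params.scale_features else Xa
    neighbors = _knn_indices(Xs, k, params.metric)
    votes_for_majority = (y[neighbors] == majority).sum(axis=1)
    vote_label = np.where(
        votes_for_majority * 2 > k,
        majority,
        np.where(votes_for_majority * 2 < k, minority, y),
    )
    misclassified = vote_label != y

    a1 = set(np.nonzero(misclassified & (y == majority))[0].tolist())
    a2: set[int] = set()
    for i in np.nonzero(misclassified & (y == minority))[0]:
        for j in neighbors[i]:
            if y[j] == majority:
                a2.add(int(j))

    removed = sorted(a1 | a2)
    keep = np.ones(len(y), dtype=bool)
    keep[removed] = False
    if is_frame:
        return X.loc[keep], y[keep], removed
    return Xa[keep], y[keep], removed


def random_undersample(X, y, ratio: float = 1.0, seed: int = 0):
    """Uniformly subsample the majority class to ``ratio`` x minority size.

    Returns (X', y', removed_indices); reproducible under ``seed``.
    """
    is_frame = isinstance(X, pd.DataFrame)
    Xa = _as_array(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    counts = {c: int((y == c).sum()) for c in classes}
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    n_keep = int(round(ratio * counts[minority]))
    if n_keep < 1 or n_keep > counts[majority]:
        raise ValueError(
            f"target majority size {n_keep} infeasible "
            f"(majority has {counts[majority]}, minority {counts[minority]})"
        )
    rng = np.random.default_rng(seed)
    majority_idx = np.nonzero(y == majority)[0]
    kept = rng.choice(majority_idx, size=n_keep, replace=False)
    keep = np.zeros(len(y), dtype=bool)
    keep[y == minority] = True
    keep[kept] = True
    removed = sorted(set(majority_idx.tolist()) - set(kept.tolist()))
    if is_frame:
        return X.loc[keep], y[keep], removed
    return Xa[keep], y[keep], removed
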