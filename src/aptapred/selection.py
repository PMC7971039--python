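"""Random-forest feature ranking and top-N selection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

DEFAULT_N_TREES = 300
DEFAULT_MAX_DEPTH = 9
DEFAULT_TOP_N = 193


@dataclass
class FeatureRanking:
    """Features ordered by non-increasing importance; scores sum to 1."""

    features: list[str]
    importances: np.ndarray
    n_trees: int
    max_depth: int
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.importances < 0):
            raise ValueError("importances must be non-negative")
        if np.any(np.diff(self.importances) > 1e-12):
            raise ValueError("importances must be non-increasing")

    def top(self, n: int) -> list[str]:
        if n > len(self.features):
            raise ValueError(f"requested top {n} of {len(self.features)} features")
        return self.features[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.features) + 1),
                "feature": self.features,
                "importance": self.importances,
            }
        )


def rank_features(
    X,
    y,
    n_trees: int = DEFAULT_N_TREES,
    max_depth: int = DEFAULT_MAX_DEPTH,
    seed: int = 0,
    method: str = "impurity",
) -> FeatureRanking:
    """Rank columns by random-forest importance.

    Default importance is mean impurity (Gini) decrease; ``method``
    "permutation" uses permutation importance instead (clipped at 0 so the
    non-negativity invariant holds). Ties are broken by column index.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need samples from both classes to rank features")

    forest = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed
    )
    forest.fit(Xa, y)
    if method == "impurity":
        scores = forest.feature_importances_
    elif method == "permutation":
        result = permutation_importance(forest, Xa, y, random_state=seed, n_repeats=5)
        scores = np.clip(result.importances_mean, 0.0, None)
        total = scores.sum()
        scores = scores / total if total > 0 else np.full_like(scores, 1 / len(scores))
    else:
        raise ValueError(f"unknown importance method {method!r}")

    order = np.lexsort((np.arange(len(scores)), -scores))
    return FeatureRanking(
        features=[names[i] for i in order],
        importances=scores[order],
        n_trees=n_trees,
        max_depth=max_depth,
        seed=seed,
    )


def select_top(X, ranking: FeatureRanking, n: int = DEFAULT_TOP_N):
    """Restrict a feature matrix to the n top-ranked columns.

    Pure column filter: row count and values are untouched, and the
    selected columns keep their original relative order.
    """
    chosen = set(ranking.top(n))
    if isinstance(X, pd.DataFrame):
        keep = [c for c in X.columns if str(c) in chosen]
        return X[keep]
    Xa = np.asarray(X)
    name_to_idx = {f"f{i}": i for i in range(Xa.shape[1])}
    idx = sorted(name_to_idx[f] for f in chosen)
    return Xa[:, idx]
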