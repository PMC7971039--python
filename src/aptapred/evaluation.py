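"""Confusion-matrix metrics, ROC/AUC and stratified k-fold cross-validation.

Cross-validation fits the whole configured pipeline (balancing, feature
ranking/selection, classifier) on the training folds only; the held-out
fold is encoded but never used for fitting, so the leakage guard in the
test suite can assert disjointness from the fold records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import balancing, selection
from .balancing import NCLParams
from .model import MLP, MLPConfig, baseline_fit_predict


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in (("tp", self.tp), ("fp", self.fp), ("tn", self.tn), ("fn", self.fn)):
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    f1: float
    mcc: float
    specificity: float
    sensitivity: float
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
        }


def confusion(y_true, y_prob, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts under predicted = (probability >= threshold)."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if len(y_true) != len(y_prob):
        raise ValueError(f"length mismatch: {len(y_true)} labels vs {len(y_prob)} scores")
    if np.any((y_prob < 0) | (y_prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = y_prob >= threshold
    pos = y_true == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float, name: str, warnings: list[str]) -> float:
    if den == 0:
        warnings.append(f"{name} undefined (zero denominator)")
        return math.nan
    return num / den


def metrics(c: ConfusionCounts, as_printed_f1: bool = False) -> MetricSet:
    """All six metrics from a confusion table.

    F1 defaults to the standard harmonic mean 2*P*S/(P+S); with
    ``as_printed_f1`` the factor 2 is dropped (P*S/(P+S)). Zero-denominator
    ratios come back as NaN with a warning recorded on the result.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    warns: list[str] = []
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    accuracy = (tp + tn) / c.total
    precision = _ratio(tp, tp + fp, "precision", warns)
    sensitivity = _ratio(tp, tp + fn, "sensitivity", warns)
    specificity = _ratio(tn, tn + fp, "specificity", warns)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        warns.append("f1 undefined (zero denominator)")
        f1 = math.nan
    else:
        f1 = precision * sensitivity / (precision + sensitivity)
        if not as_printed_f1:
            f1 *= 2.0
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        warns.append("mcc undefined (zero denominator)")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricSet(
        accuracy=accuracy,
        precision=precision,
        f1=f1,
        mcc=mcc,
        specificity=specificity,
        sensitivity=sensitivity,
        warnings=tuple(warns),
    )


def f1_macro(c: ConfusionCounts) -> float:
    """Unweighted mean of per-class F1 (positive and negative class)."""
    pos = metrics(c).f1
    neg = metrics(ConfusionCounts(tp=c.tn, fp=c.fn, tn=c.tp, fn=c.fp)).f1
    return (pos + neg) / 2.0


def roc_auc(y_true, y_prob):
    """Threshold-sweep ROC curve and trapezoid-rule area.

    Returns (points, area) where points is a DataFrame with columns
    fpr/tpr/threshold.
    """
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(y_true, np.asarray(y_prob, dtype=float))
    area = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, area


@dataclass
class PipelineSpec:
    """What to run inside each cross-validation training fold."""

    balance: str = "ncl"  # ncl | random | none
    ncl_params: NCLParams = field(default_factory=NCLParams)
    undersample_ratio: float = 1.0
    select_n: int | None = selection.DEFAULT_TOP_N
    rf_trees: int = selection.DEFAULT_N_TREES
    rf_max_depth: int = selection.DEFAULT_MAX_DEPTH
    classifier: str = "mlp"  # mlp | knn | rf | svm | snn
    mlp: MLPConfig = field(default_factory=MLPConfig)

    def __post_init__(self) -> None:
        if self.balance not in ("ncl", "random", "none"):
            raise ValueError(f"balance must be ncl/random/none, got {self.balance!r}")


@dataclass
class FoldResult:
    fold: int
    train_index: np.ndarray
    test_index: np.ndarray
    removed_by_balancing: list[int]
    selected_features: list[str] | None
    metrics: MetricSet
    f1_macro: float
    auc: float
    roc_points: pd.DataFrame


@dataclass
class CVReport:
    folds: list[FoldResult]
    mean: MetricSet
    mean_auc: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mean": self.mean.as_dict(),
            "mean_auc": self.mean_auc,
            "folds": [
                {
                    "fold": f.fold,
                    "n_train": len(f.train_index),
                    "n_test": len(f.test_index),
                    "n_removed_by_balancing": len(f.removed_by_balancing),
                    "auc": f.auc,
                    "f1_macro": f.f1_macro,
                    **f.metrics.as_dict(),
                }
                for f in self.folds
            ],
        }


def _fit_predict_fold(X_train, y_train, X_test, spec: PipelineSpec, seed: int):
    """Balance, select and train on the training fold; score the test fold."""
    removed: list[int] = []
    if spec.balance == "ncl":
        X_train, y_train, removed = balancing.ncl_resample(X_train, y_train, spec.ncl_params)
    elif spec.balance == "random":
        X_train, y_train, removed = balancing.random_undersample(
            X_train, y_train, ratio=spec.undersample_ratio, seed=seed
        )

    selected: list[str] | None = None
    if spec.select_n is not None:
        n = min(spec.select_n, X_train.shape[1])
        ranking = selection.rank_features(
            X_train, y_train, n_trees=spec.rf_trees, max_depth=spec.rf_max_depth, seed=seed
        )
        X_train = selection.select_top(X_train, ranking, n)
        X_test = selection.select_top(X_test, ranking, n)
        selected = (
            [str(c) for c in X_train.columns]
            if isinstance(X_train, pd.DataFrame)
            else ranking.top(n)
        )

    if spec.classifier == "mlp":
        cfg = replace(spec.mlp, seed=seed)
        net = MLP(cfg, n_inputs=X_train.shape[1])
        net.fit(X_train, y_train)
        probs = net.predict_proba(X_test)
    else:
        probs, _ = baseline_fit_predict(spec.classifier, X_train, y_train, X_test, seed=seed)
    return probs, removed, selected


def cross_validate(X, y, spec: PipelineSpec | None = None, folds: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation of the configured pipeline.

    Every sample lands in exactly one test fold; balancing and selection are
    fitted on the training folds only. Mean metrics are the arithmetic means
    of the per-fold values.
    """
    spec = spec or PipelineSpec()
    y = np.asarray(y)
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    class_counts = np.bincount(y.astype(int))
    if np.any(class_counts[class_counts > 0] < folds):
        raise ValueError(f"need at least {folds} samples per class, got {class_counts}")

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_results: list[FoldResult] = []
    for fold_id, (train_idx, test_idx) in enumerate(splitter.split(Xf, y)):
        X_train, y_train = Xf.iloc[train_idx], y[train_idx]
        X_test, y_test = Xf.iloc[test_idx], y[test_idx]
        probs, removed, selected = _fit_predict_fold(
            X_train, y_train, X_test, spec, seed=seed + fold_id
        )
        counts = confusion(y_test, probs)
        roc_points, auc = roc_auc(y_test, probs)
        fold_results.append(
            FoldResult(
                fold=fold_id,
                train_index=train_idx,
                test_index=test_idx,
                removed_by_balancing=removed,
                selected_features=selected,
                metrics=metrics(counts),
                f1_macro=f1_macro(counts),
                auc=auc,
                roc_points=roc_points,
            )
        )

    per_metric = {
        name: float(np.mean([f.metrics.as_dict()[name] for f in fold_results]))
        for name in fold_results[0].metrics.as_dict()
    }
    mean = MetricSet(**per_metric)
    mean_auc = float(np.mean([f.auc for f in fold_results]))
    return CVReport(folds=fold_results, mean=mean, mean_auc=mean_auc, seed=seed)
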