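import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

from aptapred import selection
from aptapred.evaluation import (
    ConfusionCounts,
    MetricSet,
    PipelineSpec,
    confusion,
    cross_validate,
    f1_macro,
    metrics,
    roc_auc,
)
from aptapred.model import MLPConfig


class TestConfusion:
    def test_perfect_probabilities(self):
        c = confusion([1, 1, 0, 0], [1.0, 1.0, 0.0, 0.0])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_all_predicted_positive(self):
        c = confusion([1, 0, 1], [0.9, 0.8, 0.7])
        assert c.tn == 0 and c.fn == 0

    def test_hand_count(self):
        c = confusion([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion([1, 0], [0.5])

    def test_probability_range_checked(self):
        with pytest.raises(ValueError, match="probabilities"):
            confusion([1, 0], [1.5, 0.2])

    def test_total_equals_sample_count(self):
        c = confusion([1, 0, 1, 0, 1], [0.6, 0.6, 0.4, 0.4, 0.9])
        assert c.total == 5


class TestMetrics:
    def test_all_cells_one(self):
        m = metrics(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        assert m.accuracy == pytest.approx(0.5, abs=1e-12)
        assert m.mcc == pytest.approx(0.0, abs=1e-12)
        assert m.precision == pytest.approx(0.5, abs=1e-12)
        assert m.sensitivity == pytest.approx(0.5, abs=1e-12)
        assert m.specificity == pytest.approx(0.5, abs=1e-12)
        assert m.f1 == pytest.approx(0.5, abs=1e-12)

    def test_perfect_confusion(self):
        m = metrics(ConfusionCounts(tp=5, fp=0, tn=7, fn=0))
        for value in (m.accuracy, m.precision, m.f1, m.mcc, m.specificity, m.sensitivity):
            assert value == pytest.approx(1.0, abs=1e-12)

    def test_undefined_specificity_flagged_nan(self):
        m = metrics(ConfusionCounts(tp=3, fp=0, tn=0, fn=1))
        assert math.isnan(m.specificity)
        assert any("specificity" in w for w in m.warnings)

    def test_as_printed_f1_halves_standard(self):
        c = ConfusionCounts(tp=8, fp=2, tn=6, fn=4)
        assert metrics(c, as_printed_f1=True).f1 == pytest.approx(metrics(c).f1 / 2)

    def test_empty_table_error(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionCounts(0, 0, 0, 0))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sklearn_on_random_labelings(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, size=200)
        y_prob = rng.random(200)
        y_pred = (y_prob >= 0.5).astype(int)
        m = metrics(confusion(y_true, y_prob))
        assert m.accuracy == pytest.approx(accuracy_score(y_true, y_pred), abs=1e-12)
        assert m.precision == pytest.approx(precision_score(y_true, y_pred), abs=1e-12)
        assert m.sensitivity == pytest.approx(recall_score(y_true, y_pred), abs=1e-12)
        assert m.f1 == pytest.approx(f1_score(y_true, y_pred), abs=1e-12)
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_f1_macro_matches_sklearn(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 2, size=150)
        y_prob = rng.random(150)
        ours = f1_macro(confusion(y_true, y_prob))
        theirs = f1_score(y_true, (y_prob >= 0.5).astype(int), average="macro")
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_mcc_zero_when_prediction_independent(self):
        m = metrics(ConfusionCounts(tp=10, fp=10, tn=10, fn=10))
        assert m.mcc == pytest.approx(0.0, abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        _, area = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert area == pytest.approx(1.0)

    def test_negated_scores_symmetry(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=100)
        s = rng.random(100)
        _, a = roc_auc(y, s)
        _, a_neg = roc_auc(y, 1 - s)
        assert a_neg == pytest.approx(1 - a, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_null_scores_near_half(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=2000)
        s = rng.random(2000)
        _, area = roc_auc(y, s)
        assert 0.45 <= area <= 0.55

    def test_matches_sklearn(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=300)
        s = rng.random(300)
        _, area = roc_auc(y, s)
        assert area == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_curve_points_schema(self):
        points, _ = roc_auc([0, 1, 0, 1], [0.2, 0.7, 0.4, 0.9])
        assert list(points.columns) == ["fpr", "tpr", "threshold"]
        assert points["fpr"].iloc[0] == 0.0
        assert points["fpr"].iloc[-1] == 1.0


FAST_SPEC = PipelineSpec(
    balance="ncl",
    select_n=10,
    rf_trees=20,
    classifier="mlp",
    mlp=MLPConfig(layer_sizes=(16, 8, 8, 8, 4, 4, 1), dropout_rate=0.0,
                  learning_rate=0.003, batch_size=64, epochs=25, seed=0),
)


@pytest.fixture
def cv_data(rng):
    n = 120
    y = np.array([1] * 40 + [0] * 80)
    X = rng.normal(size=(n, 15))
    X[:, 0] += y * 2.0
    frame = pd.DataFrame(X, columns=[f"g{i}" for i in range(15)],
                         index=[f"pair{i}" for i in range(n)])
    return frame, y


class TestCrossValidate:
    def test_every_sample_tested_exactly_once(self, cv_data):
        X, y = cv_data
        report = cross_validate(X, y, FAST_SPEC, folds=5, seed=0)
        tested = np.concatenate([f.test_index for f in report.folds])
        assert sorted(tested.tolist()) == list(range(len(X)))

    def test_fold_sizes_differ_at_most_one(self, cv_data):
        X, y = cv_data
        report = cross_validate(X, y, FAST_SPEC, folds=5, seed=0)
        sizes = [len(f.test_index) for f in report.folds]
        assert max(sizes) - min(sizes) <= 1
        assert len(report.folds) == 5

    def test_mean_is_arithmetic_mean_of_folds(self, cv_data):
        X, y = cv_data
        report = cross_validate(X, y, FAST_SPEC, folds=5, seed=0)
        for name, value in report.mean.as_dict().items():
            per_fold = [f.metrics.as_dict()[name] for f in report.folds]
            assert value == pytest.approx(np.mean(per_fold), abs=1e-12)
        assert report.mean_auc == pytest.approx(
            np.mean([f.auc for f in report.folds]), abs=1e-12
        )

    def test_leakage_guard(self, cv_data, monkeypatch):
        """Balancing and selection must only ever see training-fold rows."""
        X, y = cv_data
        seen_by_ranker = []
        real_rank = selection.rank_features

        def spy(Xf, yf, **kwargs):
            seen_by_ranker.append(set(Xf.index))
            return real_rank(Xf, yf, **kwargs)

        monkeypatch.setattr("aptapred.evaluation.selection.rank_features", spy)
        report = cross_validate(X, y, FAST_SPEC, folds=5, seed=0)
        assert len(seen_by_ranker) == 5
        for fold, seen in zip(report.folds, seen_by_ranker):
            test_ids = set(X.index[fold.test_index])
            assert not (seen & test_ids), "selection saw held-out rows"
            assert seen <= set(X.index[fold.train_index])

    def test_balancing_only_removes_training_rows(self, cv_data):
        X, y = cv_data
        report = cross_validate(X, y, FAST_SPEC, folds=5, seed=0)
        for fold in report.folds:
            # removed indices are positions within the training fold
            assert all(0 <= i < len(fold.train_index) for i in fold.removed_by_balancing)

    def test_deterministic_under_seed(self, cv_data):
        X, y = cv_data
        r1 = cross_validate(X, y, FAST_SPEC, folds=5, seed=3)
        r2 = cross_validate(X, y, FAST_SPEC, folds=5, seed=3)
        assert r1.mean.as_dict() == pytest.approx(r2.mean.as_dict(), abs=1e-12)

    def test_baseline_classifier_route(self, cv_data):
        X, y = cv_data
        spec = PipelineSpec(balance="none", select_n=None, classifier="rf")
        report = cross_validate(X, y, spec, folds=5, seed=0)
        assert 0.0 <= report.mean_auc <= 1.0

    def test_too_few_samples_error(self):
        X = np.zeros((6, 2))
        y = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="at least"):
            cross_validate(X, y, FAST_SPEC, folds=5, seed=0)

    def test_metrics_from_table_equal_metrics_from_raw(self, cv_data):
        X, y = cv_data
        report = cross_validate(X, y, FAST_SPEC, folds=5, seed=0)
        fold = report.folds[0]
        assert fold.metrics.accuracy <= 1.0 and fold.metrics.accuracy >= 0.0


def test_pipeline_spec_validation():
    with pytest.raises(ValueError, match="balance"):
        PipelineSpec(balance="smote")
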