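"""SMOTE, stratified folds, metric formulas, and the stacked classifier."""

import numpy as np
import pandas as pd
import pytest
from sklearn.datasets import make_blobs
from sklearn.neighbors import NearestNeighbors

from diabkit.metrics import (
    ClassAbsentError,
    classification_metrics,
    confusion_matrix,
    macro_roc,
)
from diabkit.stacking import (
    FoldError,
    StackConfig,
    StackedHbA1cModel,
    smote_oversample,
    stratified_folds,
)


def imbalanced_data(counts=(21, 15, 52), d=6, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(sum(counts), d))
    y = np.concatenate([np.full(c, i) for i, c in enumerate(counts)])
    return X, y


def on_segment(point, a, b, tol=1e-9):
    """Is `point` on the segment [a, b]?"""
    ab, ap = b - a, point - a
    denom = ab @ ab
    if denom == 0:
        return np.allclose(point, a, atol=tol)
    lam = (ap @ ab) / denom
    return (-tol <= lam <= 1 + tol) and np.allclose(a + lam * ab, point, atol=1e-8)


class TestSmote:
    def test_balances_to_majority_count(self):
        X, y = imbalanced_data()
        X2, y2 = smote_oversample(X, y, k_neighbors=5, seed=0)
        assert dict(zip(*np.unique(y2, return_counts=True))) == {0: 52, 1: 52, 2: 52}

    def test_originals_preserved_verbatim(self):
        X, y = imbalanced_data()
        X2, y2 = smote_oversample(X, y, k_neighbors=5, seed=0)
        assert np.array_equal(X2[: len(X)], X)
        assert np.array_equal(y2[: len(y)], y)

    def test_balanced_input_unchanged(self):
        X, y = imbalanced_data(counts=(20, 20, 20))
        X2, y2 = smote_oversample(X, y, seed=0)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_synthetics_lie_on_neighbour_segments(self):
        X, y = imbalanced_data(seed=3)
        k = 5
        X2, y2 = smote_oversample(X, y, k_neighbors=k, seed=1)
        for c in (0, 1):
            members = X[y == c]
            nn = NearestNeighbors(n_neighbors=k + 1).fit(members)
            hood = nn.kneighbors(members, return_distance=False)[:, 1:]
            synth = X2[len(X):][y2[len(X):] == c]
            for s in synth:
                ok = any(
                    on_segment(s, members[i], members[j])
                    for i in range(len(members))
                    for j in hood[i]
                )
                assert ok, "synthetic point off every neighbour segment"

    def test_two_point_minority_interpolates_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[10 + i, 0.0] for i in range(8)])
        y = np.array([0, 0] + [1] * 8)
        X2, y2 = smote_oversample(X, y, k_neighbors=1, seed=0)
        synth = X2[10:][y2[10:] == 0]
        assert len(synth) == 6
        for s in synth:
            assert on_segment(s, np.array([0.0, 0.0]), np.array([1.0, 1.0]))

    def test_class_too_small_for_k(self):
        X, y = imbalanced_data(counts=(3, 52, 52))
        with pytest.raises(FoldError, match="smaller k"):
            smote_oversample(X, y, k_neighbors=5, seed=0)

    def test_deterministic_per_seed(self):
        X, y = imbalanced_data()
        a = smote_oversample(X, y, seed=7)
        b = smote_oversample(X, y, seed=7)
        assert np.array_equal(a[0], b[0])


class TestStratifiedFolds:
    def test_divisible_case_exact(self):
        y = np.repeat([0, 1, 2], 30)
        plan = stratified_folds(y, K=3, seed=0)
        assert (plan.class_proportions().to_numpy() == 10).all()

    def test_imbalanced_within_one_of_proportional(self):
        y = np.concatenate([np.zeros(21), np.ones(15), np.full(52, 2)])
        plan = stratified_folds(y, K=4, seed=0)
        props = plan.class_proportions().to_numpy()
        ideal = np.array([21, 15, 52]) / 4
        assert np.all(np.abs(props - ideal) <= 1.0)

    def test_same_seed_identical_plan(self):
        y = np.concatenate([np.zeros(21), np.ones(15), np.full(52, 2)])
        a = stratified_folds(y, K=5, seed=3)
        b = stratified_folds(y, K=5, seed=3)
        for fa, fb in zip(a.folds, b.folds):
            assert np.array_equal(fa, fb)

    def test_folds_partition_samples(self):
        y = np.concatenate([np.zeros(21), np.ones(15), np.full(52, 2)])
        plan = stratified_folds(y, K=4, seed=1)
        flat = np.sort(np.concatenate(plan.folds))
        assert np.array_equal(flat, np.arange(88))


class TestMetricFormulas:
    def brute_force(self, cm):
        n = cm.shape[0]
        tp = [cm[i, i] for i in range(n)]
        fn = [cm[i, :].sum() - cm[i, i] for i in range(n)]
        fp = [cm[:, i].sum() - cm[i, i] for i in range(n)]
        acc = sum(tp) / sum(tp[i] + fn[i] for i in range(n))
        prec = sum((tp[i] / (tp[i] + fp[i])) if tp[i] + fp[i] else 0.0 for i in range(n)) / n
        rec = sum(tp[i] / (tp[i] + fn[i]) for i in range(n)) / n
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        return acc, prec, rec, f1

    def labels_from_cm(self, cm):
        y_true, y_pred = [], []
        for i in range(cm.shape[0]):
            for j in range(cm.shape[1]):
                y_true += [i] * cm[i, j]
                y_pred += [j] * cm[i, j]
        return np.array(y_true), np.array(y_pred)

    def test_matches_contingency_oracle(self):
        cm = np.array([[5, 0, 0], [1, 3, 1], [0, 0, 2]])
        y_true, y_pred = self.labels_from_cm(cm)
        rep = classification_metrics(y_true, y_pred)
        acc, prec, rec, f1 = self.brute_force(cm)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.macro_precision == pytest.approx(prec)
        assert rep.macro_recall == pytest.approx(rec)
        assert rep.macro_f1 == pytest.approx(f1)

    def test_random_matrices_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cm = rng.integers(0, 20, size=(3, 3))
            cm += np.eye(3, dtype=int)  # every class occurs in y_true
            y_true, y_pred = self.labels_from_cm(cm)
            rep = classification_metrics(y_true, y_pred)
            acc, prec, rec, f1 = self.brute_force(cm)
            assert (rep.accuracy, rep.macro_precision, rep.macro_recall,
                    rep.macro_f1) == (acc, prec, rec, f1)

    def test_perfect_predictions(self):
        y = np.repeat([0, 1, 2], 5)
        rep = classification_metrics(y, y)
        assert rep.accuracy == rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0

    def test_absent_class_raises_not_nan(self):
        with pytest.raises(ClassAbsentError):
            classification_metrics([0, 0, 1], [0, 1, 1], classes=[0, 1, 2])

    def test_macro_f1_bounded_by_components(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y_true = rng.integers(0, 3, 60)
            y_pred = rng.integers(0, 3, 60)
            if len(np.unique(y_true)) < 3:
                continue
            rep = classification_metrics(y_true, y_pred)
            assert rep.macro_f1 <= max(rep.macro_precision, rep.macro_recall) + 1e-12

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        y_true = np.concatenate([np.full(10, c) for c in range(3)])
        y_pred = rng.integers(0, 3, 30)
        rep1 = classification_metrics(y_true, y_pred)
        perm = {0: 2, 1: 0, 2: 1}
        rep2 = classification_metrics(
            [perm[c] for c in y_true], [perm[c] for c in y_pred]
        )
        assert rep1.accuracy == pytest.approx(rep2.accuracy)
        assert rep1.macro_f1 == pytest.approx(rep2.macro_f1)

    def test_chance_level_limits(self):
        rng = np.random.default_rng(1)
        n = 30_000
        y_true = rng.integers(0, 3, n)
        y_pred = rng.integers(0, 3, n)
        rep = classification_metrics(y_true, y_pred)
        assert rep.accuracy == pytest.approx(1 / 3, abs=0.02)
        proba = rng.dirichlet(np.ones(3), size=n)
        _, _, auc = macro_roc(y_true, proba, classes=np.array([0, 1, 2]))
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_confusion_counts_sum_identity(self):
        rng = np.random.default_rng(2)
        y_true = np.concatenate([np.full(c, i) for i, c in enumerate((21, 15, 52))])
        y_pred = rng.integers(0, 3, 88)
        classes, cm = confusion_matrix(y_true, y_pred)
        tp = np.diag(cm)
        fn = cm.sum(axis=1) - tp
        fp = cm.sum(axis=0) - tp
        assert (tp + fn).sum() == (tp + fp).sum() == 88


class TestStackedModel:
    def test_separable_blobs_high_accuracy(self):
        X, y = make_blobs(
            n_samples=150, centers=3, cluster_std=0.6, random_state=0
        )
        cfg = StackConfig(seed=0, svc_select_k=0, et_select_k=0)
        model = StackedHbA1cModel(X[:105], y[:105], config=cfg)
        results = model.fit()
        acc = (results.predict(X[105:]) == y[105:]).mean()
        assert acc >= 0.95

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        with pytest.raises(FoldError):
            StackedHbA1cModel(X, np.zeros(30, dtype=int))

    def test_same_seed_identical_predictions(self):
        X, y = imbalanced_data(counts=(15, 15, 25), d=8, seed=2)
        X[y == 1] += 1.5
        cfg = StackConfig(seed=4)
        p1 = StackedHbA1cModel(X, y, config=cfg).fit().predict_proba(X)
        p2 = StackedHbA1cModel(X, y, config=cfg).fit().predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_meta_features_dimension(self):
        X, y = imbalanced_data(counts=(15, 15, 25), d=8, seed=2)
        results = StackedHbA1cModel(X, y, config=StackConfig(seed=0)).fit()
        assert results.meta_features(X).shape == (55, 9)

    def test_feature_count_mismatch_rejected(self):
        X, y = imbalanced_data(counts=(15, 15, 25), d=8, seed=2)
        results = StackedHbA1cModel(X, y, config=StackConfig(seed=0)).fit()
        with pytest.raises(ValueError, match="feature count"):
            results.predict_proba(X[:, :4])

    def test_cross_validate_report_structure(self):
        X, y = imbalanced_data(counts=(15, 12, 33), d=10, seed=5)
        X[y == 0, 0] += 2.0
        model = StackedHbA1cModel(X, y, config=StackConfig(seed=1, outer_k=3))
        rep = model.cross_validate()
        assert rep.confusion.sum() == 60
        assert len(rep.fold_metrics) == 3
        assert 0.0 <= rep.auc <= 1.0
        # SMOTE leakage audit: validation indices never fed the oversampler
        for tr_idx, fold in zip(rep.oversampling_inputs, rep.plan.folds):
            assert len(np.intersect1d(tr_idx, fold)) == 0

    def test_summary_mentions_architecture(self):
        X, y = imbalanced_data(counts=(15, 15, 25), d=8, seed=2)
        results = StackedHbA1cModel(X, y, config=StackConfig(seed=0)).fit()
        text = results.summary()
        assert "xgb" in text and "svc" in text and "et" in text and "KNN" in text
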