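"""Metrics, ROC/AUC, F-score ranking, cross-validation, and ablation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from lncstpred import (
    BalancingPlan,
    ablation,
    confusion_metrics,
    fscore,
    roc_auc,
    stratified_kfold_cv,
)
from lncstpred.features import feature_manifest


def binary_labels(tp=50, fn=10, fp=5, tn=100):
    y_true = ["pos"] * (tp + fn) + ["neg"] * (fp + tn)
    y_pred = ["pos"] * tp + ["neg"] * fn + ["pos"] * fp + ["neg"] * tn
    return np.array(y_true), np.array(y_pred)


class TestConfusionMetrics:
    def test_hand_evaluated_counts(self):
        y_true, y_pred = binary_labels()
        rep = confusion_metrics(y_true, y_pred, ["neg", "pos"])
        row = rep.per_class.loc["pos"]
        assert (row.TP, row.FN, row.FP, row.TN) == (50, 10, 5, 100)
        assert row.Sn == pytest.approx(50 / 60, abs=5e-5)
        assert row.Sp == pytest.approx(100 / 105, abs=5e-5)
        assert row.MCC == pytest.approx(4950 / np.sqrt(55 * 60 * 105 * 110), abs=1e-9)
        assert rep.acc == pytest.approx(150 / 165)

    def test_perfect_predictions(self):
        y = np.array(["a", "b", "c", "a", "b", "c"])
        rep = confusion_metrics(y, y, ["a", "b", "c"])
        assert rep.acc == 1.0
        assert (rep.per_class[["Sn", "Sp", "MCC"]] == 1.0).all().all()

    def test_degenerate_all_one_class_mcc_zero(self):
        y_true = np.array(["a", "a", "b", "b"])
        y_pred = np.array(["a", "a", "a", "a"])
        rep = confusion_metrics(y_true, y_pred, ["a", "b"])
        assert rep.per_class.loc["a", "MCC"] == 0.0
        assert rep.per_class.loc["b", "MCC"] == 0.0

    def test_confusion_sums_and_count_identity(self, rng):
        y_true = rng.choice(["a", "b", "c"], 100)
        y_pred = rng.choice(["a", "b", "c"], 100)
        rep = confusion_metrics(y_true, y_pred, ["a", "b", "c"])
        assert rep.confusion.to_numpy().sum() == 100
        pc = rep.per_class
        assert ((pc.TP + pc.FN + pc.FP + pc.TN) == 100).all()
        assert rep.acc == pytest.approx((y_true == y_pred).mean())

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array(["a"]), np.array(["a", "b"]), ["a", "b"])


class TestRocAuc:
    def test_perfect_and_inverted_scores(self):
        y = np.array(["pos"] * 5 + ["neg"] * 5)
        s_pos = np.array([0.9, 0.8, 0.85, 0.95, 0.7, 0.1, 0.2, 0.3, 0.15, 0.05])
        scores = np.column_stack([1 - s_pos, s_pos])
        aucs, macro = roc_auc(y, scores, ["neg", "pos"])
        assert aucs["pos"] == 1.0 and aucs["neg"] == 1.0
        flipped = np.column_stack([s_pos, 1 - s_pos])
        aucs2, _ = roc_auc(y, flipped, ["neg", "pos"])
        assert aucs2["pos"] == 0.0

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(10, 100))
            y = rng.choice(["pos", "neg"], n)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            scores = np.column_stack([1 - s, s])
            aucs, _ = roc_auc(y, scores, ["neg", "pos"])
            u = mannwhitneyu(s[y == "pos"], s[y == "neg"]).statistic
            expected = u / ((y == "pos").sum() * (y == "neg").sum())
            assert aucs["pos"] == pytest.approx(expected, abs=1e-10)

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["pos", "neg"], 200)
        s = rng.random(200)
        aucs, macro = roc_auc(y, np.column_stack([1 - s, s]), ["neg", "pos"])
        assert aucs["pos"] == pytest.approx(0.5, abs=0.08)

    def test_class_without_positives_excluded_from_macro(self):
        y = np.array(["a", "a", "b", "b"])
        scores = np.column_stack([[0.9, 0.8, 0.1, 0.2],
                                  [0.1, 0.2, 0.9, 0.8],
                                  [0.0, 0.0, 0.0, 0.0]])
        aucs, macro = roc_auc(y, scores, ["a", "b", "c"])
        assert aucs["c"] is None
        assert macro == pytest.approx(1.0)


def naive_fscore(X, y):
    """Independent literal re-implementation of the F statistic."""
    classes = sorted(set(y))
    out = []
    for i in range(X.shape[1]):
        xbar = X[:, i].mean()
        num = den = 0.0
        for c in classes:
            xc = X[np.asarray(y) == c, i]
            num += (xc.mean() - xbar) ** 2
            den += ((xc - xc.mean()) ** 2).sum() / (len(xc) - 1)
        out.append(num / den if den else num / 1e-12)
    return np.array(out)


class TestFscore:
    def test_hand_example(self):
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        y = np.array(["c1", "c1", "c2", "c2"])
        ranking = fscore(X, y)
        assert ranking.scores[0] == pytest.approx(2.0)

    def test_constant_feature_scores_zero(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = np.array(["a"] * 3 + ["b"] * 3)
        assert fscore(X, y).scores[0] == pytest.approx(0.0)

    def test_matches_naive_reimplementation(self, rng):
        X = rng.normal(size=(30, 20))
        y = rng.choice(["a", "b", "c"], 30)
        while min(np.unique(y, return_counts=True)[1]) < 2:
            y = rng.choice(["a", "b", "c"], 30)
        got = fscore(X, y).scores
        expected = naive_fscore(X, y)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_scale_and_shift_invariance(self, rng):
        X = rng.normal(size=(24, 8))
        y = rng.choice(["a", "b"], 24)
        base = fscore(X, y).scores
        np.testing.assert_allclose(fscore(3.7 * X - 2.0, y).scores, base, rtol=1e-9)

    def test_small_class_errors(self):
        X = np.zeros((3, 2))
        y = np.array(["a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            fscore(X, y)

    def test_rank_order_descending_with_index_tiebreak(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.choice(["a", "b"], 20)
        r = fscore(X, y)
        assert sorted(r.order.tolist()) == list(range(5))
        scores_in_order = r.scores[r.order]
        assert (np.diff(scores_in_order) <= 1e-15).all()


def blob_frame(rng, n_per_class=30, n_classes=3, noise=1.0):
    X = np.vstack(
        [rng.normal(i * 3, noise, (n_per_class, 4)) for i in range(n_classes)]
    )
    y = np.repeat([f"c{i}" for i in range(n_classes)], n_per_class)
    return X, y


class TestCrossValidation:
    def test_every_sample_tested_once_and_stratified(self, rng):
        X, y = blob_frame(rng)
        report, logs = stratified_kfold_cv(X, y, folds=5, n_rounds=5, seed=0)
        assert report.confusion.to_numpy().sum() == len(y)
        assert len(logs) == 5

    def test_folds_reduced_with_warning_for_tiny_class(self, rng):
        X, y = blob_frame(rng, n_per_class=30)
        X = np.vstack([X, rng.normal(9, 1.0, (3, 4))])
        y = np.concatenate([y, ["tiny"] * 3])
        with pytest.warns(UserWarning, match="reducing folds"):
            report, logs = stratified_kfold_cv(X, y, folds=10, n_rounds=5, seed=0)
        assert len(logs) == 3

    def test_in_fold_balancing_never_contaminates_test_folds(self, rng):
        """Synthetic points enter training portions only: pooled predictions
        cover exactly the real samples, and class counts stay real."""
        X, y = blob_frame(rng, n_per_class=12)
        X = np.vstack([X, rng.normal(9, 1.0, (4, 4))])
        y = np.concatenate([y, ["tiny"] * 4])
        plan = BalancingPlan(targets={"tiny": 12}, seed=0)
        with pytest.warns(UserWarning):
            report, logs = stratified_kfold_cv(
                X, y, folds=5, plan=plan, n_rounds=5, seed=0
            )
        assert report.confusion.to_numpy().sum() == len(y)
        assert report.confusion.loc["tiny"].sum() == 4
        assert any(log["balance"] for log in logs)

    def test_two_classes_required(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            stratified_kfold_cv(X, np.array(["a"] * 10), folds=2)


class TestAblation:
    def make_frame(self, rng):
        """3-mer block pure noise; frame-2 RF block carries the class."""
        n, names = 90, feature_manifest(("3mer", "3rf"))
        y = np.repeat(["a", "b", "c"], 30)
        X = rng.random((n, len(names))) * 0.02
        rf2 = [i for i, c in enumerate(names) if c.startswith("RF2:")]
        for k, cls in enumerate(["a", "b", "c"]):
            X[y == cls, rf2[2 * k]] += 0.5
        frame = pd.DataFrame(X, columns=names)
        frame["label"] = y
        return frame

    def test_informative_subset_strictly_improves(self, rng):
        frame = self.make_frame(rng)
        table = ablation(
            frame,
            {
                "3mer": feature_manifest(("3mer",)),
                "3mer+3rf": feature_manifest(("3mer", "3rf")),
            },
            folds=3, n_rounds=10, seed=0,
        )
        assert table.loc["3mer+3rf", "ACC"] > table.loc["3mer", "ACC"]

    def test_single_subset_single_row(self, rng):
        frame = self.make_frame(rng)
        table = ablation(
            frame, {"3mer": feature_manifest(("3mer",))},
            folds=3, n_rounds=5, seed=0,
        )
        assert list(table.index) == ["3mer"]

    def test_unknown_feature_errors(self, rng):
        frame = self.make_frame(rng)
        with pytest.raises(ValueError, match="unknown features"):
            ablation(frame, {"bad": ["nope"]}, folds=3)
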