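"""Oversampling, uncertainty filtering, outlier removal, diagnostics."""

import numpy as np
import pytest

from lncstpred import (
    BalancingPlan,
    adasyn,
    borderline_smote,
    cluster_diagnostics,
    equalizing_plan,
    execute_plan,
    remove_outliers,
    uncertainty_filter,
)
from lncstpred.balance import adasyn_allocation, danger_set


def toy_boundary():
    """Two minority points with majority neighbours crowding one of them."""
    X = np.array(
        [[0.0, 0.0], [1.0, 0.0],
         [0.4, 0.1], [0.5, -0.1], [0.6, 0.1], [5.0, 5.0]]
    )
    y = np.array(["min", "min", "maj", "maj", "maj", "maj"])
    return X, y


class TestDangerSet:
    def test_matches_brute_force_knn(self):
        X, y = toy_boundary()
        plan = BalancingPlan(danger_m=5)
        got = set(danger_set(X, y, "min", plan))
        # brute force: m nearest neighbours by Euclidean distance, self excluded
        expected = set()
        for i in np.flatnonzero(y == "min"):
            d = np.linalg.norm(X - X[i], axis=1)
            order = [j for j in np.argsort(d, kind="stable") if j != i][:5]
            n_maj = sum(y[j] != "min" for j in order)
            if 5 / 2 <= n_maj < 5:
                expected.add(i)
        assert got == expected
        assert got  # toy is constructed so DANGER is non-empty

    def test_safe_points_excluded(self):
        # minority cluster far from majority: all neighbours minority => safe
        X = np.vstack([np.random.default_rng(0).normal(0, 0.1, (6, 2)),
                       np.full((6, 2), 10.0)])
        y = np.array(["min"] * 6 + ["maj"] * 6)
        assert len(danger_set(X, y, "min", BalancingPlan(danger_m=3))) == 0


class TestBorderlineSmote:
    def test_synthetic_points_on_parent_segment(self):
        X, y = toy_boundary()
        plan = BalancingPlan(targets={"min": 9}, danger_m=3, smote_k=2, seed=3)
        samples, log = borderline_smote(X, y, plan, "min")
        assert len(samples) == log["deficit"] == 7
        ids = {str(i): X[i] for i in range(len(y))}
        for s in samples:
            pi, pz = ids[s.parent_i], ids[s.parent_zi]
            np.testing.assert_array_equal(s.features, pi + s.u * (pz - pi))

    def test_deficit_zero_returns_nothing(self):
        X, y = toy_boundary()
        samples, log = borderline_smote(
            X, y, BalancingPlan(targets={"min": 2}), "min"
        )
        assert samples == [] and log["deficit"] == 0

    def test_fallback_to_classic_smote_logged(self):
        X = np.vstack([np.random.default_rng(1).normal(0, 0.1, (5, 2)),
                       np.full((5, 2), 10.0)])
        y = np.array(["min"] * 5 + ["maj"] * 5)
        plan = BalancingPlan(targets={"min": 8}, danger_m=3, seed=0)
        samples, log = borderline_smote(X, y, plan, "min")
        assert log["fallback"] is True
        assert len(samples) == 3

    def test_singleton_class_errors(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        y = np.array(["min", "maj", "maj"])
        with pytest.raises(ValueError, match="fewer than 2"):
            borderline_smote(X, y, BalancingPlan(targets={"min": 5}), "min")

    def test_convex_combination_preserves_block_normalization(self, rng):
        """Each 64-block of an interpolation of two normalized blocks sums to 1."""
        def norm_rows(n):
            m = rng.random((n, 64))
            return m / m.sum(axis=1, keepdims=True)

        X = np.hstack([norm_rows(12), norm_rows(12)])
        y = np.array(["min"] * 4 + ["maj"] * 8)
        plan = BalancingPlan(targets={"min": 10}, danger_m=3, seed=0)
        samples, _ = borderline_smote(X, y, plan, "min")
        for s in samples:
            assert s.features[:64].sum() == pytest.approx(1.0, abs=1e-9)
            assert s.features[64:].sum() == pytest.approx(1.0, abs=1e-9)


class TestAdasyn:
    def test_allocation_toy_matches_hand_computation(self):
        # r = (1.0, 0.2, 0.0), deficit 6: raw = (5.0, 1.0, 0.0) -> (5, 1, 0)
        np.testing.assert_array_equal(
            adasyn_allocation(np.array([1.0, 0.2, 0.0]), 6), [5, 1, 0]
        )

    def test_allocation_residue_to_highest_r(self):
        # raw = (2.4, 2.4, 1.2) -> rounds to (2, 2, 1), residue 1 -> highest r
        g = adasyn_allocation(np.array([0.4, 0.4, 0.2]), 6)
        assert g.sum() == 6
        assert g[0] == 3 and g[1] == 2 and g[2] == 1

    def test_all_zero_r_uniform_fallback(self):
        g = adasyn_allocation(np.zeros(4), 6)
        assert g.sum() == 6
        assert set(g) <= {1, 2}

    def test_total_synthesized_equals_deficit(self):
        X, y = toy_boundary()
        plan = BalancingPlan(targets={"min": 11}, danger_m=3, smote_k=2, seed=7)
        samples, log = adasyn(X, y, plan, "min")
        assert len(samples) == 9
        assert sum(log["allocation"]) == 9

    def test_segment_identity(self):
        X, y = toy_boundary()
        plan = BalancingPlan(targets={"min": 8}, danger_m=3, smote_k=2, seed=5)
        samples, _ = adasyn(X, y, plan, "min")
        for s in samples:
            pi, pz = X[int(s.parent_i)], X[int(s.parent_zi)]
            np.testing.assert_array_equal(s.features, pi + s.u * (pz - pi))


class TestUncertaintyFilter:
    def blob_data(self, rng):
        Xa = rng.normal(0, 0.3, (30, 3))
        Xb = rng.normal(5, 0.3, (30, 3))
        return np.vstack([Xa, Xb]), np.array(["a"] * 30 + ["b"] * 30)

    def test_infinite_tau_no_vote_check_retains_all(self, rng):
        X, y = self.blob_data(rng)
        plan = BalancingPlan(targets={"a": 40}, seed=0)
        samples, _ = execute_plan(X, y, plan)
        retained, log = uncertainty_filter(
            X, y, samples, tau=np.inf, majority_check=False, seed=0
        )
        assert len(retained) == len(samples)

    def test_unambiguous_samples_have_zero_entropy(self, rng):
        X, y = self.blob_data(rng)
        plan = BalancingPlan(targets={"a": 40}, seed=0)
        samples, _ = execute_plan(X, y, plan)
        retained, _ = uncertainty_filter(X, y, samples, seed=0)
        # well-separated blobs: every interpolation is deep inside class a
        assert len(retained) == len(samples)
        assert all(s.uncertainty == pytest.approx(0.0) for s in retained)

    def test_deterministic_given_seed(self, rng):
        X, y = self.blob_data(rng)
        plan = BalancingPlan(targets={"a": 45}, seed=1)
        samples, _ = execute_plan(X, y, plan)
        r1, _ = uncertainty_filter(X, y, list(samples), seed=9)
        r2, _ = uncertainty_filter(X, y, list(samples), seed=9)
        assert [id(s) for s in r1] == [id(s) for s in r2]


class TestRemoveOutliers:
    def test_distant_point_removed(self, rng):
        X = np.vstack([rng.uniform(0, 1, (20, 2)), [[100.0, 100.0]]])
        y = np.array(["a"] * 21)
        kept = remove_outliers(X, y, z=3.0)
        assert 20 not in kept
        assert len(kept) == 20

    def test_identical_points_collapse_to_one(self):
        X = np.ones((5, 3))
        y = np.array(["a"] * 5)
        kept = remove_outliers(X, y)
        assert list(kept) == [0]

    def test_identity_when_disabled(self, rng):
        X = rng.normal(size=(15, 4))
        y = np.array(["a"] * 15)
        kept = remove_outliers(X, y, z=np.inf, eps=0.0)
        assert list(kept) == list(range(15))


class TestClusterDiagnostics:
    def test_separated_blobs_give_pure_clusters(self, rng):
        centers = np.eye(5) * 50
        X = np.vstack([rng.normal(c, 0.5, (20, 5)) for c in centers])
        y = np.repeat([f"c{i}" for i in range(5)], 20)
        out = cluster_diagnostics(X, y, n_clusters=5, seed=0)
        cont = out["contingency"].to_numpy()
        assert (np.sort(cont.max(axis=0)) == 20).all()  # each class one cluster
        assert ((cont > 0).sum(axis=1) == 1).all()      # each cluster pure

    def test_single_cluster(self, rng):
        X = rng.normal(size=(10, 3))
        out = cluster_diagnostics(X, n_clusters=1, seed=0)
        assert len(set(out["cluster_labels"])) == 1

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 4))
        l1 = cluster_diagnostics(X, n_clusters=3, seed=4)["cluster_labels"]
        l2 = cluster_diagnostics(X, n_clusters=3, seed=4)["cluster_labels"]
        assert (l1 == l2).all()


class TestEqualizingPlan:
    def test_targets_shape(self):
        y = np.array(["a"] * 100 + ["b"] * 60 + ["c"] * 4)
        plan = equalizing_plan(y)
        # minorities raised toward second-largest (60); tiny class capped 20x
        assert plan.targets == {"c": 60}
        y2 = np.array(["a"] * 100 + ["b"] * 60 + ["c"] * 2)
        assert equalizing_plan(y2).targets == {"c": 40}
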