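"""Modified multiclass AdaBoost.

The round coefficient keeps the classic binary 1/2-factor but adds the
multiclass offset:

    alpha_t = 1/2 * ln((1 - eps_t) / eps_t) + ln(k - 1)

(natural logarithm; for k = 2 this reduces to the classic binary AdaBoost
coefficient). Sample weights are multiplied by exp(-alpha_t) when correct
and exp(+alpha_t) when wrong, then renormalized to sum to 1 each round.
Training stops early when alpha_t <= 0, i.e. when the weighted error
reaches the positivity boundary eps = (k-1)^2 / ((k-1)^2 + 1). Note this
boundary is stricter for large errors than the usual multiclass "better
than 1/k" requirement; it is a direct consequence of retaining the
1/2-factor alongside the ln(k-1) offset, and is enforced as such.

Base learners are depth-limited decision trees fitted with the current
sample weights. Prediction is the alpha-weighted vote; ties break toward
the earlier class in the model's ordered class set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeClassifier
from sklearn.tree._tree import TREE_LEAF


def alpha(epsilon: float, k: int) -> float:
    """Round coefficient alpha(eps, k) = 1/2 ln((1-eps)/eps) + ln(k-1)."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie strictly in (0, 1)")
    if k < 2:
        raise ValueError("k must be >= 2")
    return 0.5 * math.log((1.0 - epsilon) / epsilon) + math.log(k - 1)


def alpha_positivity_boundary(k: int) -> float:
    """Weighted error at which alpha crosses zero: (k-1)^2 / ((k-1)^2 + 1)."""
    q = (k - 1) ** 2
    return q / (q + 1)


@dataclass
class ModifiedAdaBoost:
    """Multiclass AdaBoost with the ln(k-1)-offset round coefficient.

    Parameters
    ----------
    n_rounds:
        Maximum number of boosting rounds T.
    depth:
        Maximum depth of the decision-tree base learner.
    eps_floor:
        Weighted errors are clamped to [eps_floor, 1 - eps_floor] before
        computing alpha, so a perfectly fit round yields a large finite
        coefficient instead of an infinite one.
    seed:
        Seeds the base-learner tie-breaking; training is deterministic
        given (data order, seed).

    After :meth:`fit`, ``rounds_`` holds (tree, alpha) pairs, ``classes_``
    the ordered class set, and ``history_`` per-round diagnostics
    (epsilon, alpha, weight sum after renormalization).
    """

    n_rounds: int = 100
    depth: int = 2
    eps_floor: float = 1e-10
    seed: int = 0

    rounds_: list[tuple[DecisionTreeClassifier, float]] = field(
        default_factory=list, repr=False
    )
    classes_: np.ndarray | None = field(default=None, repr=False)
    history_: list[dict] = field(default_factory=list, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ModifiedAdaBoost":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        k = len(classes)
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.rounds_ = []
        self.history_ = []
        self.classes_ = classes
        for t in range(self.n_rounds):
            tree = DecisionTreeClassifier(
                max_depth=self.depth, random_state=self.seed
            )
            tree.fit(X, y, sample_weight=w)
            pred = tree.predict(X)
            wrong = pred != y
            eps = float(np.clip(w[wrong].sum(), self.eps_floor, 1 - self.eps_floor))
            a = alpha(eps, k)
            if a <= 0:
                if t == 0:
                    raise ValueError(
                        "first base learner no better than the multiclass "
                        f"positivity boundary (eps = {eps:.4f})"
                    )
                break
            self.rounds_.append((tree, a))
            w = w * np.where(wrong, math.exp(a), math.exp(-a))
            w = w / w.sum()
            self.history_.append(
                {"round": t, "epsilon": eps, "alpha": a, "weight_sum": float(w.sum())}
            )
            if eps <= self.eps_floor:
                break  # base learner already perfect; nothing left to reweight
        return self

    # -- prediction --------------------------------------------------------

    def _check_fitted(self) -> None:
        if self.classes_ is None or not self.rounds_:
            raise ValueError("model is not fitted")

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Raw alpha-weighted vote totals, shape (n_samples, k)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.rounds_[0][0].n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"({self.rounds_[0][0].n_features_in_})"
            )
        class_pos = {c: i for i, c in enumerate(self.classes_)}
        scores = np.zeros((len(X), len(self.classes_)))
        for tree, a in self.rounds_:
            pred = tree.predict(X)
            for i, p in enumerate(pred):
                scores[i, class_pos[p]] += a
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weighted-vote labels; ties break toward the earlier class."""
        scores = self.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores normalized by total alpha; rows sum to 1."""
        scores = self.decision_scores(X)
        total = sum(a for _, a in self.rounds_)
        return scores / total

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Serialize the fitted model (trees as nested split records)."""
        self._check_fitted()
        payload = {
            "class_set": [str(c) for c in self.classes_],
            "config": {
                "n_rounds": self.n_rounds,
                "depth": self.depth,
                "eps_floor": self.eps_floor,
                "seed": self.seed,
            },
            "rounds": [
                {"alpha": a, "tree": _tree_to_dict(tree)}
                for tree, a in self.rounds_
            ],
            "history": self.history_,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "_LoadedBoostModel":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        model = _LoadedBoostModel(
            n_rounds=cfg["n_rounds"],
            depth=cfg["depth"],
            eps_floor=cfg["eps_floor"],
            seed=cfg["seed"],
        )
        model.classes_ = np.array(payload["class_set"])
        model.history_ = payload["history"]
        model._trees = [
            (_DictTree(r["tree"], model.classes_), r["alpha"])
            for r in payload["rounds"]
        ]
        return model


def _tree_to_dict(tree: DecisionTreeClassifier) -> dict:
    t = tree.tree_
    classes = tree.classes_

    def node(i: int) -> dict:
        if t.children_left[i] == TREE_LEAF:
            values = t.value[i][0]
            return {"leaf": str(classes[int(np.argmax(values))])}
        return {
            "feature": int(t.feature[i]),
            "threshold": float(t.threshold[i]),
            "left": node(t.children_left[i]),
            "right": node(t.children_right[i]),
        }

    return {"n_features": int(tree.n_features_in_), "root": node(0)}


class _DictTree:
    """Replayable decision tree reloaded from JSON split records."""

    def __init__(self, payload: dict, classes: np.ndarray):
        self.root = payload["root"]
        self.n_features_in_ = payload["n_features"]
        self.classes_ = classes

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = []
        for row in np.asarray(X, dtype=float):
            node = self.root
            while "leaf" not in node:
                node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
            out.append(node["leaf"])
        return np.array(out)


class _LoadedBoostModel(ModifiedAdaBoost):
    """A model reloaded from JSON; predicts via replayed split records."""

    _trees: list[tuple[_DictTree, float]]

    @property
    def rounds_(self):  # type: ignore[override]
        return self._trees

    @rounds_.setter
    def rounds_(self, value):
        self._trees = value

    def fit(self, X, y):  # pragma: no cover - loaded models are frozen
        raise NotImplementedError("loaded models cannot be refitted")
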