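"""Class balancing for the predictive dataset.

Minority classes are oversampled with Borderline-SMOTE (type 1) or ADASYN,
both authored here so that every synthetic point records its parents and
interpolation coefficient exactly. Synthetic points can then be filtered by
an ensemble-uncertainty criterion, outliers removed per class, and the
result inspected with a K-means / PCA diagnostic.

Distances are Euclidean. When the feature layout includes an MFE column
(kcal/mol scale, which would otherwise dominate the frequency features),
callers should pass its index via ``BalancingPlan.scale_columns`` so it is
standardized to zero mean / unit variance before neighbour searches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier


@dataclass
class BalancingPlan:
    """How each class should be oversampled.

    targets:
        Per-class post-oversampling counts; must be >= the current count
        for every class listed. Classes not listed are left alone.
    smote_k:
        Number of minority neighbours used for interpolation.
    danger_m:
        Neighbourhood size for borderline/difficulty detection.
    method:
        Per-class choice, ``"borderline-smote"`` or ``"adasyn"``; classes
        not listed use ``default_method``.
    scale_columns:
        Column indices standardized before distance computations (e.g. the
        MFE column).
    """

    targets: dict[str, int] = field(default_factory=dict)
    smote_k: int = 5
    danger_m: int = 5
    method: dict[str, str] = field(default_factory=dict)
    default_method: str = "borderline-smote"
    scale_columns: tuple[int, ...] = ()
    seed: int = 0

    def method_for(self, cls: str) -> str:
        return self.method.get(cls, self.default_method)


@dataclass
class SyntheticSample:
    """One interpolated sample with full provenance."""

    features: np.ndarray
    parent_i: str
    parent_zi: str
    u: float
    cls: str
    uncertainty: float | None = None


def equalizing_plan(
    y: np.ndarray,
    cap_factor: float = 20.0,
    **kwargs,
) -> BalancingPlan:
    """Raise every minority class toward the second-largest class count.

    Tiny classes are capped at ``cap_factor`` times their original size so
    that a handful of real points is never asked to span hundreds of
    synthetic ones.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    second = int(np.sort(counts)[-2]) if len(counts) > 1 else int(counts[0])
    targets = {}
    for c, n in zip(classes, counts):
        goal = min(second, int(math.floor(cap_factor * n)))
        if goal > n:
            targets[str(c)] = goal
    return BalancingPlan(targets=targets, **kwargs)


def _scaled(X: np.ndarray, plan: BalancingPlan) -> np.ndarray:
    if not plan.scale_columns:
        return X
    Xs = X.astype(float).copy()
    for c in plan.scale_columns:
        col = Xs[:, c]
        sd = col.std()
        Xs[:, c] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    return Xs


def _neighbour_labels(
    Xs: np.ndarray, y: np.ndarray, idx: np.ndarray, m: int
) -> np.ndarray:
    """Labels of the m nearest neighbours (excluding self) of each idx row."""
    nn = NearestNeighbors(n_neighbors=min(m + 1, len(Xs))).fit(Xs)
    _, neigh = nn.kneighbors(Xs[idx])
    out = []
    for row_i, row in zip(idx, neigh):
        row = [j for j in row if j != row_i][:m]
        out.append(y[row])
    return np.array(out)


def danger_set(
    X: np.ndarray, y: np.ndarray, target_class: str, plan: BalancingPlan
) -> np.ndarray:
    """Indices of borderline minority samples (the DANGER set).

    A minority sample is in DANGER when at least half but not all of its
    ``danger_m`` nearest neighbours (searched over the full dataset) belong
    to other classes.
    """
    Xs = _scaled(X, plan)
    minority_idx = np.flatnonzero(y == target_class)
    neigh_labels = _neighbour_labels(Xs, y, minority_idx, plan.danger_m)
    m = plan.danger_m
    danger = [
        i
        for i, labs in zip(minority_idx, neigh_labels)
        if m / 2 <= np.sum(labs != target_class) < m
    ]
    return np.array(danger, dtype=int)


def _interpolate(
    X: np.ndarray,
    ids: np.ndarray,
    y_cls: str,
    seeds: list[int],
    rng: np.random.Generator,
    minority_idx: np.ndarray,
    smote_k: int,
    Xs: np.ndarray,
) -> list[SyntheticSample]:
    """Draw synthetic points from each seed toward a random minority neighbour."""
    nn = NearestNeighbors(n_neighbors=min(smote_k + 1, len(minority_idx))).fit(
        Xs[minority_idx]
    )
    out: list[SyntheticSample] = []
    pos_of = {g: p for p, g in enumerate(minority_idx)}
    for i in seeds:
        _, neigh = nn.kneighbors(Xs[i][None, :])
        cand = [minority_idx[p] for p in neigh[0] if p != pos_of.get(i, -1)][:smote_k]
        zi = int(rng.choice(cand))
        u = float(rng.uniform())
        feats = X[i] + u * (X[zi] - X[i])
        out.append(SyntheticSample(feats, str(ids[i]), str(ids[zi]), u, y_cls))
    return out


def borderline_smote(
    X: np.ndarray,
    y: np.ndarray,
    plan: BalancingPlan,
    target_class: str,
    ids: np.ndarray | None = None,
) -> tuple[list[SyntheticSample], dict]:
    """Borderline-SMOTE1 oversampling of one minority class.

    Synthesizes ``plan.targets[target_class] - current`` samples by
    interpolating DANGER-set members toward their nearest minority
    neighbours with u ~ Uniform(0, 1). Falls back to classic SMOTE over all
    minority samples when the DANGER set is empty (reported in the log).
    """
    ids = np.arange(len(y)) if ids is None else np.asarray(ids)
    minority_idx = np.flatnonzero(y == target_class)
    if len(minority_idx) < 2:
        raise ValueError(f"class {target_class!r} has fewer than 2 members")
    deficit = plan.targets.get(target_class, len(minority_idx)) - len(minority_idx)
    if deficit <= 0:
        return [], {"deficit": 0, "danger_size": 0, "fallback": False}

    rng = np.random.default_rng(plan.seed)
    Xs = _scaled(X, plan)
    danger = danger_set(X, y, target_class, plan)
    fallback = len(danger) == 0
    pool = minority_idx if fallback else danger
    order = rng.permutation(pool)
    seeds = [int(order[t % len(order)]) for t in range(deficit)]
    samples = _interpolate(
        X, ids, target_class, seeds, rng, minority_idx, plan.smote_k, Xs
    )
    return samples, {
        "deficit": deficit,
        "danger_size": int(len(danger)),
        "fallback": fallback,
    }


def adasyn_allocation(r: np.ndarray, deficit: int) -> np.ndarray:
    """Integer allocation g_i = round(deficit * r_i / sum(r)).

    Rounding residue (positive or negative) is assigned to the samples with
    the highest difficulty r_i. All-zero r falls back to a uniform
    allocation.
    """
    r = np.asarray(r, dtype=float)
    if r.sum() == 0:
        base = np.full(len(r), deficit // len(r), dtype=int)
        base[: deficit % len(r)] += 1
        return base
    raw = deficit * r / r.sum()
    g = np.round(raw).astype(int)
    residue = deficit - g.sum()
    order = np.argsort(-r, kind="stable")
    step = 1 if residue > 0 else -1
    k = 0
    while residue != 0:
        i = order[k % len(order)]
        if step < 0 and g[i] == 0:
            k += 1
            continue
        g[i] += step
        residue -= step
        k += 1
    return g


def adasyn(
    X: np.ndarray,
    y: np.ndarray,
    plan: BalancingPlan,
    target_class: str,
    ids: np.ndarray | None = None,
) -> tuple[list[SyntheticSample], dict]:
    """ADASYN oversampling: difficulty-weighted allocation of synthetic points.

    Each minority sample's difficulty r_i is the fraction of its
    ``danger_m`` nearest neighbours belonging to other classes; the deficit
    is split proportionally to r and synthesized by interpolation toward
    random minority neighbours.
    """
    ids = np.arange(len(y)) if ids is None else np.asarray(ids)
    minority_idx = np.flatnonzero(y == target_class)
    if len(minority_idx) < 2:
        raise ValueError(f"class {target_class!r} has fewer than 2 members")
    deficit = plan.targets.get(target_class, len(minority_idx)) - len(minority_idx)
    if deficit <= 0:
        return [], {"deficit": 0, "fallback": False}

    rng = np.random.default_rng(plan.seed)
    Xs = _scaled(X, plan)
    neigh_labels = _neighbour_labels(Xs, y, minority_idx, plan.danger_m)
    r = np.array(
        [np.sum(labs != target_class) / plan.danger_m for labs in neigh_labels]
    )
    fallback = r.sum() == 0
    g = adasyn_allocation(r, deficit)
    seeds: list[int] = []
    for i, gi in zip(minority_idx, g):
        seeds.extend([int(i)] * int(gi))
    samples = _interpolate(
        X, ids, target_class, seeds, rng, minority_idx, plan.smote_k, Xs
    )
    return samples, {
        "deficit": deficit,
        "r": r.tolist(),
        "allocation": g.tolist(),
        "fallback": bool(fallback),
    }


def execute_plan(
    X: np.ndarray,
    y: np.ndarray,
    plan: BalancingPlan,
    ids: np.ndarray | None = None,
) -> tuple[list[SyntheticSample], dict]:
    """Oversample every class listed in the plan with its chosen method."""
    all_samples: list[SyntheticSample] = []
    log: dict = {}
    for cls in sorted(plan.targets):
        method = plan.method_for(cls)
        fn = borderline_smote if method == "borderline-smote" else adasyn
        samples, info = fn(X, y, plan, cls, ids)
        info["method"] = method
        log[cls] = info
        all_samples.extend(samples)
    return all_samples, log


def uncertainty_filter(
    X_real: np.ndarray,
    y_real: np.ndarray,
    synthetic: list[SyntheticSample],
    tau: float | None = None,
    ensemble_size: int = 25,
    seed: int = 0,
    majority_check: bool = True,
    max_depth: int = 3,
) -> tuple[list[SyntheticSample], dict]:
    """Filter synthetic samples by ensemble vote entropy.

    An ensemble of shallow decision trees is trained on bootstrap resamples
    of the real data only. Each synthetic sample receives the vote entropy
    H = -sum_c p_c ln p_c (nats); samples with H > tau, or whose majority
    vote disagrees with their assigned class (when ``majority_check``), are
    discarded. Default tau is 0.75 * ln(k) for k observed classes.

    This is an entropy-based uncertainty weighting of the synthetic pool —
    one concrete reading of "uncertain weight" filtering, and deliberately
    conservative: it only ever removes synthetic points, never real ones.
    """
    classes = np.unique(y_real)
    if tau is None:
        tau = 0.75 * math.log(len(classes))
    if not synthetic:
        return [], {"retained": 0, "discarded_entropy": 0, "discarded_vote": 0}
    rng = np.random.default_rng(seed)
    Xsyn = np.vstack([s.features for s in synthetic])
    votes = np.zeros((len(synthetic), len(classes)))
    class_pos = {c: i for i, c in enumerate(classes)}
    n = len(y_real)
    for b in range(ensemble_size):
        boot = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_depth=max_depth, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X_real[boot], y_real[boot])
        pred = tree.predict(Xsyn)
        for i, p in enumerate(pred):
            votes[i, class_pos[p]] += 1
    p = votes / ensemble_size
    with np.errstate(divide="ignore", invalid="ignore"):
        H = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    majority = classes[np.argmax(votes, axis=1)]

    retained: list[SyntheticSample] = []
    disc_h = disc_v = 0
    for i, s in enumerate(synthetic):
        s.uncertainty = float(H[i])
        if H[i] > tau:
            disc_h += 1
        elif majority_check and majority[i] != s.cls:
            disc_v += 1
        else:
            retained.append(s)
    return retained, {
        "retained": len(retained),
        "discarded_entropy": disc_h,
        "discarded_vote": disc_v,
        "tau": tau,
    }


def remove_outliers(
    X: np.ndarray,
    y: np.ndarray,
    z: float = 3.0,
    eps: float = 1e-9,
) -> np.ndarray:
    """Per-class centroid-distance outlier removal plus near-duplicate collapse.

    Within each class, samples farther than mean + z*sd of the centroid
    distances are removed; afterwards any sample within ``eps`` (Euclidean)
    of an earlier retained sample is dropped as a near-duplicate. Returns
    the retained row indices in original order.
    """
    keep_mask = np.ones(len(y), dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            continue
        centroid = X[idx].mean(axis=0)
        d = np.linalg.norm(X[idx] - centroid, axis=1)
        cutoff = d.mean() + z * d.std()
        keep_mask[idx[d > cutoff]] = False

    retained: list[int] = []
    kept_rows: list[np.ndarray] = []
    for i in np.flatnonzero(keep_mask):
        if eps > 0 and any(
            np.linalg.norm(X[i] - prev) <= eps for prev in kept_rows
        ):
            continue
        retained.append(i)
        kept_rows.append(X[i])
    return np.array(retained, dtype=int)


def cluster_diagnostics(
    X: np.ndarray,
    y: np.ndarray | None = None,
    n_clusters: int = 5,
    seed: int = 0,
) -> dict:
    """K-means clustering plus a 2-D PCA projection for visual QC.

    Returns cluster labels, the first two principal-component coordinates,
    and (when true labels are given) a cluster-by-class contingency table.
    """
    if n_clusters > len(X):
        raise ValueError("n_clusters exceeds number of samples")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    pca = PCA(n_components=min(2, X.shape[1]), random_state=seed)
    proj = pca.fit_transform(X)
    out = {"cluster_labels": labels, "pca": proj}
    if y is not None:
        out["contingency"] = pd.crosstab(
            pd.Series(labels, name="cluster"), pd.Series(y, name="class")
        )
    return out
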