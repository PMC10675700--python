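"""From-scratch random-forest regressor: bagged CART trees, averaged.

Each tree is grown greedily: at a node the builder draws a random feature
subset of size ``ceil(max_features · p)``, scans every midpoint between
consecutive distinct sorted values of each candidate feature, and takes the
split with the largest sum-of-squared-error reduction (ties broken toward
the lowest feature index, then the lowest threshold).  Recursion stops at
``max_depth``, when a child would fall under ``min_samples_leaf``, or when
the node's targets have zero variance; a leaf predicts the mean of its
training targets.  The forest trains each tree on a bootstrap sample of
size n drawn with replacement from its own seeded substream and predicts
the mean over trees — so every prediction stays inside the training-target
range.

The split scan and tree growth run under numba for speed; the recursion is
an explicit stack over (start, end) index ranges, sklearn-style.

Randomness contract: one root seed deterministically derives a bootstrap
stream and a per-tree split-subsampling seed; no global state is touched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import ConfigurationError, ShapeMismatchError

__all__ = [
    "ForestHyperparams",
    "Tree",
    "ForestModel",
    "fit_tree",
    "fit_forest",
    "predict",
]

_UNLIMITED_DEPTH = 1 << 30


@dataclass(frozen=True)
class ForestHyperparams:
    """The tunable knobs of the forest — the genes the optimizer searches.

    max_depth=None means unlimited; max_features is the fraction of
    features considered per split (subset redrawn at every split).
    """

    n_trees: int = 100
    max_depth: int | None = None
    min_samples_leaf: int = 1
    max_features: float = 1.0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.max_depth is not None and self.max_depth < 1:
            raise ConfigurationError(
                f"max_depth must be >= 1 or None, got {self.max_depth}")
        if self.min_samples_leaf < 1:
            raise ConfigurationError(
                f"min_samples_leaf must be >= 1, got {self.min_samples_leaf}")
        if not 0.0 < self.max_features <= 1.0:
            raise ConfigurationError(
                f"max_features must lie in (0, 1], got {self.max_features}")

    def to_dict(self) -> dict:
        return {"n_trees": self.n_trees, "max_depth": self.max_depth,
                "min_samples_leaf": self.min_samples_leaf,
                "max_features": self.max_features}


@njit(cache=True)
def _grow_tree(X, y, max_depth, min_samples_leaf, m_features, seed):  # pragma: no cover - numba
    n, p = X.shape
    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    value = np.zeros(max_nodes)
    count = np.zeros(max_nodes, np.int64)

    np.random.seed(seed)
    idx = np.arange(n)
    feat_pool = np.arange(p)
    stack = np.empty((max_nodes, 4), np.int64)  # node, start, end, depth
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    stack[0, 3] = 0
    sp = 1
    n_nodes = 1

    while sp > 0:
        sp -= 1
        node = stack[sp, 0]
        start = stack[sp, 1]
        end = stack[sp, 2]
        depth = stack[sp, 3]
        nn = end - start

        s = 0.0
        ss = 0.0
        for t in range(start, end):
            yt = y[idx[t]]
            s += yt
            ss += yt * yt
        value[node] = s / nn
        count[node] = nn
        sse = ss - s * s / nn
        if depth >= max_depth or nn < 2 * min_samples_leaf or sse <= 1e-12:
            continue

        # per-split random feature subset (Fisher-Yates prefix), scanned in
        # ascending feature order for the deterministic tie-break
        if m_features < p:
            for a in range(m_features):
                b = a + np.random.randint(0, p - a)
                tmp = feat_pool[a]
                feat_pool[a] = feat_pool[b]
                feat_pool[b] = tmp
            sub = np.sort(feat_pool[:m_features].copy())
        else:
            sub = np.arange(p)

        # a replacement must beat the incumbent by >1e-12 so that float
        # summation-order noise cannot override the documented tie-break
        # (lowest feature index, then lowest threshold)
        base = s * s / nn
        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        vbuf = np.empty(nn)
        ybuf = np.empty(nn)
        for fi in range(sub.shape[0]):
            fcol = sub[fi]
            for t in range(nn):
                vbuf[t] = X[idx[start + t], fcol]
            order = np.argsort(vbuf, kind="mergesort")
            for t in range(nn):
                ybuf[t] = y[idx[start + order[t]]]
            vs = vbuf[order]
            sl = 0.0
            for cut in range(nn - 1):
                sl += ybuf[cut]
                nl = cut + 1
                if nl < min_samples_leaf or nn - nl < min_samples_leaf:
                    continue
                if vs[cut] == vs[cut + 1]:
                    continue
                sr = s - sl
                gain = sl * sl / nl + sr * sr / (nn - nl) - base
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best_f = fcol
                    best_thr = 0.5 * (vs[cut] + vs[cut + 1])
        if best_f < 0:
            continue

        # stable partition of idx[start:end] by the chosen split
        tmp_l = np.empty(nn, np.int64)
        tmp_r = np.empty(nn, np.int64)
        kl = 0
        kr = 0
        for t in range(start, end):
            if X[idx[t], best_f] <= best_thr:
                tmp_l[kl] = idx[t]
                kl += 1
            else:
                tmp_r[kr] = idx[t]
                kr += 1
        for t in range(kl):
            idx[start + t] = tmp_l[t]
        for t in range(kr):
            idx[start + kl + t] = tmp_r[t]

        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feature[node] = best_f
        threshold[node] = best_thr
        left[node] = lid
        right[node] = rid
        stack[sp, 0] = lid
        stack[sp, 1] = start
        stack[sp, 2] = start + kl
        stack[sp, 3] = depth + 1
        sp += 1
        stack[sp, 0] = rid
        stack[sp, 1] = start + kl
        stack[sp, 2] = end
        stack[sp, 3] = depth + 1
        sp += 1

    return (feature[:n_nodes], threshold[:n_nodes], left[:n_nodes],
            right[:n_nodes], value[:n_nodes], count[:n_nodes])


@dataclass(frozen=True)
class Tree:
    """Flat-array CART tree; ``feature == -1`` marks a leaf."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    count: np.ndarray
    n_features: int

    @property
    def n_nodes(self) -> int:
        return int(self.feature.size)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _check_X(X, self.n_features)
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            rows = np.nonzero(active)[0]
            cur = node[rows]
            go_left = X[rows, self.feature[cur]] <= self.threshold[cur]
            node[rows[go_left]] = self.left[cur[go_left]]
            node[rows[~go_left]] = self.right[cur[~go_left]]
            active = self.feature[node] >= 0
        return self.value[node]

    def to_lists(self) -> dict:
        return {"feature": self.feature.tolist(),
                "threshold": self.threshold.tolist(),
                "left": self.left.tolist(),
                "right": self.right.tolist(),
                "value": self.value.tolist(),
                "count": self.count.tolist(),
                "n_features": self.n_features}

    @classmethod
    def from_lists(cls, d: dict) -> "Tree":
        return cls(feature=np.asarray(d["feature"], np.int64),
                   threshold=np.asarray(d["threshold"], float),
                   left=np.asarray(d["left"], np.int64),
                   right=np.asarray(d["right"], np.int64),
                   value=np.asarray(d["value"], float),
                   count=np.asarray(d["count"], np.int64),
                   n_features=int(d["n_features"]))


def _check_Xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ConfigurationError(
            f"X must be a nonempty n×p table, got shape {X.shape}")
    if y.shape != (X.shape[0],):
        raise ShapeMismatchError(
            f"y length {y.shape} does not match X rows {X.shape[0]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ConfigurationError("X and y must be finite")
    return X, y


def _check_X(X, n_features: int) -> np.ndarray:
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != n_features:
        raise ShapeMismatchError(
            f"probe features {X.shape} do not match training p={n_features}")
    return X


def fit_tree(X, y, params: ForestHyperparams, seed: int = 0) -> Tree:
    """Grow one CART regression tree on (X, y) with seeded feature subsets."""
    params.validate()
    X, y = _check_Xy(X, y)
    p = X.shape[1]
    m = max(1, math.ceil(params.max_features * p))
    depth = _UNLIMITED_DEPTH if params.max_depth is None else params.max_depth
    arrays = _grow_tree(X, y, depth, params.min_samples_leaf, m,
                        int(seed) & 0x7FFFFFFF)
    return Tree(*arrays, n_features=p)


@dataclass(frozen=True)
class ForestModel:
    trees: tuple
    params: ForestHyperparams
    feature_names: tuple
    seed: int

    def predict(self, X) -> np.ndarray:
        X = _check_X(X, self.trees[0].n_features)
        acc = np.zeros(X.shape[0])
        for tree in self.trees:
            acc += tree.predict(X)
        return acc / len(self.trees)

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(),
                "feature_names": list(self.feature_names),
                "seed": self.seed,
                "trees": [t.to_lists() for t in self.trees]}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ForestModel":
        return cls(trees=tuple(Tree.from_lists(t) for t in d["trees"]),
                   params=ForestHyperparams(**d["params"]),
                   feature_names=tuple(d["feature_names"]),
                   seed=int(d["seed"]))

    @classmethod
    def from_json(cls, s: str) -> "ForestModel":
        return cls.from_dict(json.loads(s))


def fit_forest(X, y, params: ForestHyperparams, seed: int = 0,
               feature_names=None, bootstrap: bool = True,
               bootstrap_indices=None) -> ForestModel:
    """Train the ensemble: seeded bootstrap per tree, averaged predictions.

    ``bootstrap=False`` trains every tree on the full sample (test hook);
    ``bootstrap_indices`` — a list of n_trees index arrays — injects the
    resampling externally (cross-implementation comparisons).
    """
    params.validate()
    X, y = _check_Xy(X, y)
    n = X.shape[0]
    if bootstrap_indices is not None and len(bootstrap_indices) != params.n_trees:
        raise ConfigurationError(
            "bootstrap_indices must supply one index array per tree")
    rng = np.random.default_rng(seed)
    trees = []
    for t in range(params.n_trees):
        tree_seed = int(rng.integers(0, 2**31 - 1))
        if bootstrap_indices is not None:
            take = np.asarray(bootstrap_indices[t], dtype=np.int64)
        elif bootstrap:
            take = rng.integers(0, n, size=n)
        else:
            take = np.arange(n)
        trees.append(fit_tree(X[take], y[take], params, seed=tree_seed))
    names = tuple(feature_names) if feature_names is not None \
        else tuple(f"x{j}" for j in range(X.shape[1]))
    return ForestModel(trees=tuple(trees), params=params,
                       feature_names=names, seed=int(seed))


def predict(model: ForestModel, X) -> np.ndarray:
    """Functional alias for :meth:`ForestModel.predict`."""
    return model.predict(X)
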