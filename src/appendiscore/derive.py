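"""Score derivation: CART, bagged random forests, and unit-weight score building.

Re-implements the machinery used to derive simplified appendicitis scores
from binarized clinical items:

* CART — greedy binary splitting of binary features by Gini impurity gain,
  with minimal cost-complexity ("weakest link") pruning against a
  misclassification risk, governed by a complexity parameter;
* a random forest of such trees, each grown on a bootstrap resample with a
  random candidate-feature subset (``mtry``) per split, with normalized
  mean-decrease-in-impurity (Gini) feature importances;
* ``derive_score`` — repeated 70/30 train/test splitting, importance
  averaging, feature retention above a floor, and conversion of the retained
  features into a unit-weight additive score whose positivity cutoff
  maximizes the Youden index on the pooled test splits.

Everything is deterministic given the seed; Gini-gain ties break by feature
declaration order.  Features are never reused along a root-to-leaf path
(a second split on a binary feature is vacuous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .records import PatientRecord
from .scoring import DEFAULT_POLICY, FEATURES, ScoreDefinition, ThresholdPolicy, derive_features

_EPS = 1e-12


class DerivationError(RuntimeError):
    """No features survive derivation (or inputs cannot support it)."""


class _Node:
    __slots__ = ("feature", "left", "right", "n", "n_pos", "gain")

    def __init__(self, n: int, n_pos: int):
        self.feature: Optional[int] = None  # None -> leaf
        self.left: Optional["_Node"] = None   # branch for feature == 0
        self.right: Optional["_Node"] = None  # branch for feature == 1
        self.n = n
        self.n_pos = n_pos
        self.gain = 0.0  # n-weighted impurity decrease of this split

    @property
    def prob(self) -> float:
        return self.n_pos / self.n if self.n else 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _grow(X, y, idx, available, min_leaf, rng, mtry, n_root) -> _Node:
    m = idx.size
    ys = y[idx]
    c = float(ys.sum())
    node = _Node(n=m, n_pos=int(c))
    if c == 0 or c == m or m < 2 * min_leaf or not available.any():
        return node

    candidates = np.flatnonzero(available)
    if mtry is not None and candidates.size > mtry:
        candidates = np.sort(rng.choice(candidates, size=mtry, replace=False))

    Xs = X[np.ix_(idx, candidates)]
    n1 = Xs.sum(axis=0)
    c1 = ys @ Xs
    n0 = m - n1
    c0 = c - c1
    valid = (n1 >= min_leaf) & (n0 >= min_leaf)
    if not valid.any():
        return node

    with np.errstate(divide="ignore", invalid="ignore"):
        child = 2.0 * (c1 * (n1 - c1) / n1 + c0 * (n0 - c0) / n0) / m
    node_gini = 2.0 * c * (m - c) / (m * m)
    gain = np.where(valid, node_gini - child, -np.inf)
    best = int(np.argmax(gain))  # first max -> lowest feature index wins ties
    if gain[best] <= _EPS:
        return node

    j = int(candidates[best])
    node.feature = j
    node.gain = (m / n_root) * float(gain[best])
    mask = X[idx, j] > 0.5
    child_avail = available.copy()
    child_avail[j] = False
    node.left = _grow(X, y, idx[~mask], child_avail, min_leaf, rng, mtry, n_root)
    node.right = _grow(X, y, idx[mask], child_avail, min_leaf, rng, mtry, n_root)
    return node


def _leaf_risk(node: _Node, n_train: int) -> float:
    return min(node.n_pos, node.n - node.n_pos) / n_train


def _subtree_stats(node: _Node, n_train: int) -> tuple[float, int]:
    """(summed leaf risk, leaf count) of the subtree rooted at ``node``."""
    if node.is_leaf:
        return _leaf_risk(node, n_train), 1
    r_l, k_l = _subtree_stats(node.left, n_train)
    r_r, k_r = _subtree_stats(node.right, n_train)
    return r_l + r_r, k_l + k_r


def _prune(root: _Node, alpha: float, n_train: int) -> None:
    """Weakest-link cost-complexity pruning at complexity ``alpha`` (in place)."""
    while not root.is_leaf:
        weakest = None
        weakest_g = np.inf

        def visit(node: _Node) -> None:
            nonlocal weakest, weakest_g
            if node.is_leaf:
                return
            risk_sub, leaves = _subtree_stats(node, n_train)
            g = (_leaf_risk(node, n_train) - risk_sub) / (leaves - 1)
            if g < weakest_g - _EPS:
                weakest, weakest_g = node, g
            visit(node.left)
            visit(node.right)

        visit(root)
        if weakest is None or weakest_g > alpha:
            return
        weakest.feature = None
        weakest.left = weakest.right = None
        weakest.gain = 0.0


def _predict_node(node: _Node, X, idx, out) -> None:
    if node.is_leaf:
        out[idx] = node.prob
        return
    mask = X[idx, node.feature] > 0.5
    _predict_node(node.left, X, idx[~mask], out)
    _predict_node(node.right, X, idx[mask], out)


@dataclass
class DecisionTree:
    """A fitted CART over binary features."""

    root: _Node
    feature_names: tuple
    min_leaf: int
    complexity: float
    n_train: int

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        _predict_node(self.root, X, np.arange(X.shape[0]), out)
        return out

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= 0.5

    @property
    def n_leaves(self) -> int:
        return _subtree_stats(self.root, self.n_train)[1]

    @property
    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))
        return d(self.root)

    def raw_importances(self) -> np.ndarray:
        gains = np.zeros(len(self.feature_names))

        def visit(node):
            if node.is_leaf:
                return
            gains[node.feature] += node.gain
            visit(node.left)
            visit(node.right)

        visit(self.root)
        return gains

    def importances(self) -> dict:
        gains = self.raw_importances()
        total = gains.sum()
        if total > 0:
            gains = gains / total
        return dict(zip(self.feature_names, gains))


def _validate_matrix(X, y, feature_names):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) and y length n")
    if X.size and not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("features must be binary 0/1")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(X.shape[1]))
    elif len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length must match X columns")
    return X, y, tuple(feature_names)


def fit_cart(
    X,
    y,
    feature_names: Optional[Sequence[str]] = None,
    min_leaf: int = 1,
    complexity: float = 0.01,
    max_depth: Optional[int] = None,
) -> DecisionTree:
    """Fit a Gini CART on binary features and cost-complexity prune it.

    Single-class labels yield a root stump predicting that class.  With a
    positive complexity, subtrees whose per-leaf misclassification
    improvement does not exceed it are collapsed (label-independent noise
    prunes all the way to the root); at 0.0 only zero-improvement subtrees
    collapse, and a negative complexity disables pruning entirely.
    """
    X, y, names = _validate_matrix(X, y, feature_names)
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training data")
    root = _grow(X, y, np.arange(n), np.ones(X.shape[1], dtype=bool),
                 min_leaf, None, None, n)
    if max_depth is not None:
        _limit_depth(root, max_depth)
    if complexity >= 0:
        _prune(root, complexity, n)
    return DecisionTree(root=root, feature_names=names, min_leaf=min_leaf,
                        complexity=complexity, n_train=n)


def _limit_depth(node: _Node, depth: int) -> None:
    if node.is_leaf:
        return
    if depth == 0:
        node.feature = None
        node.left = node.right = None
        node.gain = 0.0
        return
    _limit_depth(node.left, depth - 1)
    _limit_depth(node.right, depth - 1)


@dataclass
class RandomForest:
    """A bagged ensemble of unpruned CARTs with per-split feature subsetting."""

    trees: list
    bootstrap_indices: list
    feature_names: tuple
    mtry: int
    seed: int
    importances: dict = field(default_factory=dict)  # normalized, sums to <= 1

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        total = np.zeros(X.shape[0])
        for tree in self.trees:
            total += tree.predict_proba(X)
        return total / len(self.trees)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= 0.5

    def oob_error(self, X, y) -> float:
        """Out-of-bag misclassification rate (majority vote over OOB trees)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        n = X.shape[0]
        prob_sum = np.zeros(n)
        counts = np.zeros(n)
        for tree, idx in zip(self.trees, self.bootstrap_indices):
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            if oob.any():
                prob_sum[oob] += tree.predict_proba(X[oob])
                counts[oob] += 1
        seen = counts > 0
        if not seen.any():
            raise ValueError("no out-of-bag observations")
        pred = (prob_sum[seen] / counts[seen]) >= 0.5
        return float(np.mean(pred != y[seen]))


def fit_forest(
    X,
    y,
    n_trees: int = 200,
    mtry: Optional[int] = None,
    min_leaf: int = 1,
    bootstrap: bool = True,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> RandomForest:
    """Fit a seeded random forest of ``n_trees`` unpruned Gini CARTs.

    Each tree trains on a bootstrap resample (size n) with ``mtry`` candidate
    features per split (default: ceil(sqrt(p))).  Feature importance is the
    total Gini decrease per feature summed over trees and normalized to 1.
    """
    X, y, names = _validate_matrix(X, y, feature_names)
    n, p = X.shape
    if n == 0:
        raise ValueError("empty training data")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    if not (1 <= mtry <= p):
        raise ValueError(f"mtry must lie in [1, {p}]")
    rng = np.random.default_rng(seed)
    trees = []
    indices = []
    gains = np.zeros(p)
    all_avail = np.ones(p, dtype=bool)
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        root = _grow(X, y, idx, all_avail.copy(), min_leaf, rng, mtry, idx.size)
        tree = DecisionTree(root=root, feature_names=names, min_leaf=min_leaf,
                            complexity=0.0, n_train=idx.size)
        gains += tree.raw_importances()
        trees.append(tree)
        indices.append(idx)
    total = gains.sum()
    importances = dict(zip(names, gains / total if total > 0 else gains))
    return RandomForest(trees=trees, bootstrap_indices=indices, feature_names=names,
                        mtry=mtry, seed=seed, importances=importances)


@dataclass
class DerivationResult:
    """Outcome of repeated-split score derivation."""

    features: tuple  # ((name, mean importance), ...) sorted by descending importance
    score_definition: ScoreDefinition
    per_repeat_metrics: list
    repeats: int
    method: str
    mean_importances: dict = field(default_factory=dict)  # all candidates


def cohort_feature_matrix(
    cohort: Sequence[PatientRecord],
    candidate_features: Optional[Sequence[str]] = None,
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Binarized complete-case feature matrix and appendicitis labels.

    Raises if any patient is missing a candidate feature or the outcome —
    derivation requires a complete-case cohort.
    """
    names = tuple(candidate_features) if candidate_features else FEATURES
    for name in names:
        if name not in FEATURES:
            raise ValueError(f"unknown candidate feature {name!r}")
    rows = []
    labels = []
    for patient in cohort:
        vector = derive_features(patient, policy)
        values = [vector[name] for name in names]
        if any(v is None for v in values):
            missing = [n for n, v in zip(names, values) if v is None]
            raise ValueError(f"patient {patient.id} incomplete for candidates: {missing}")
        if patient.appendicitis is None:
            raise ValueError(f"patient {patient.id} has no outcome label")
        rows.append(values)
        labels.append(int(patient.appendicitis))
    return np.asarray(rows, dtype=float), np.asarray(labels, dtype=float), names


def _split_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    truth = truth.astype(bool)
    pred = pred.astype(bool)
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    npos = int(truth.sum())
    nneg = truth.size - npos
    return {
        "accuracy": float(np.mean(pred == truth)),
        "sensitivity": tp / npos if npos else float("nan"),
        "specificity": tn / nneg if nneg else float("nan"),
        "n_test": int(truth.size),
    }


def derive_score(
    cohort: Sequence[PatientRecord],
    candidate_features: Optional[Sequence[str]] = None,
    method: str = "forest",
    importance_floor: float = 0.05,
    repeats: int = 20,
    train_fraction: float = 0.7,
    seed: int = 0,
    n_trees: int = 200,
    mtry: Optional[int] = None,
    min_leaf: int = 1,
    complexity: float = 0.01,
    policy: ThresholdPolicy = DEFAULT_POLICY,
    score_name: Optional[str] = None,
) -> DerivationResult:
    """Derive a unit-weight score from a cohort by CART or random forest.

    Per repeat the data is split ``train_fraction``/rest, the model fitted on
    the training part, and normalized importances plus test-split metrics
    recorded.  Features whose mean importance reaches ``importance_floor``
    are retained (sorted by descending importance) and assembled into a
    unit-weight :class:`ScoreDefinition` whose positivity cutoff maximizes
    the Youden index (sens + spec - 1) over the pooled test splits.
    """
    if method not in ("cart", "forest"):
        raise ValueError(f"unknown method {method!r}")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")

    X, y, names = cohort_feature_matrix(cohort, candidate_features, policy)
    n = X.shape[0]
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("train_fraction leaves an empty train or test split")

    rng = np.random.default_rng(seed)
    importance_sum = np.zeros(len(names))
    per_repeat = []
    pooled_test: list[np.ndarray] = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        if method == "cart":
            model = fit_cart(X[train_idx], y[train_idx], feature_names=names,
                             min_leaf=min_leaf, complexity=complexity)
        else:
            model = fit_forest(X[train_idx], y[train_idx], n_trees=n_trees,
                               mtry=mtry, min_leaf=min_leaf,
                               seed=int(rng.integers(2**31)), feature_names=names)
        imp = model.importances() if method == "cart" else model.importances
        importance_sum += np.array([imp[name] for name in names])
        per_repeat.append(_split_metrics(model.predict(X[test_idx]), y[test_idx]))
        pooled_test.append(test_idx)

    mean_imp = importance_sum / repeats
    order = np.argsort(-mean_imp, kind="stable")
    retained = [(names[j], float(mean_imp[j])) for j in order if mean_imp[j] >= importance_floor]
    if not retained:
        raise DerivationError(
            f"no feature reached importance floor {importance_floor}; "
            f"best was {names[int(order[0])]} at {mean_imp[order[0]]:.4f}"
        )

    retained_idx = [names.index(name) for name, _ in retained]
    pooled = np.concatenate(pooled_test)
    totals = X[np.ix_(pooled, retained_idx)].sum(axis=1)
    truth = y[pooled].astype(bool)
    npos = int(truth.sum())
    nneg = truth.size - npos
    best_cutoff, best_youden = 1, -np.inf
    for cutoff in range(1, len(retained) + 1):
        pred = totals >= cutoff
        sens = np.sum(pred & truth) / npos if npos else 0.0
        spec = np.sum(~pred & ~truth) / nneg if nneg else 0.0
        youden = sens + spec - 1.0
        if youden > best_youden + _EPS:
            best_cutoff, best_youden = cutoff, youden

    definition = ScoreDefinition(
        name=score_name or f"derived_{method}",
        items=tuple((name, 1) for name, _ in retained),
        positivity_cutoff=best_cutoff,
        threshold_policy=policy,
    )
    return DerivationResult(
        features=tuple(retained),
        score_definition=definition,
        per_repeat_metrics=per_repeat,
        repeats=repeats,
        method=method,
        mean_importances=dict(zip(names, mean_imp)),
    )
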