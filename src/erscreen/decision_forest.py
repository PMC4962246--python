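"""Decision Forest: an ensemble of trees on mutually exclusive descriptors.

Unlike a random forest, the Decision Forest (DF) draws no bootstrap
samples and no random feature subsets.  Every member tree is grown on the
full training set, but each successive tree may only split on descriptors
that no earlier tree used.  Growth of the ensemble stops as soon as adding
a tree no longer improves the fit on the training set.  A compound's
binder probability is the unweighted mean, over member trees, of the
binder fraction in the terminal node it falls into; the call is binder
when that mean exceeds 0.5 (a probability of exactly 0.5 is a non-binder).

Member trees are plain CART classification trees: binary splits of the
form ``x <= threshold`` chosen to minimise weighted Gini impurity, with
candidate thresholds at midpoints between consecutive distinct sorted
values.  Ties in impurity are broken deterministically: lower descriptor
column index first, then lower threshold.  Terminal probabilities are the
raw binder fraction ``n_active / n_total`` — no smoothing by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from erscreen.dataset_io import LabeledDataset

__all__ = [
    "TreeParams",
    "TreeNode",
    "DecisionTree",
    "DecisionForest",
    "fit_tree",
    "fit_forest",
    "predict_proba",
    "classify",
    "save_forest",
    "load_forest",
]


@dataclass(frozen=True)
class TreeParams:
    """Hyperparameters shared by every tree in a forest.

    Defaults are sized for training sets of a few hundred compounds: depth
    10 and leaves of at least 2 compounds give non-trivial but finite
    trees.  ``impurity`` is an identifier so an alternative criterion can
    be plugged in; only ``"gini"`` is currently implemented.
    """

    max_depth: int = 10
    min_leaf_size: int = 2
    min_split_size: int = 4
    impurity: str = "gini"
    max_trees: int = 20
    smoothing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1 or self.min_leaf_size < 1 or self.max_trees < 1:
            raise ValueError("max_depth, min_leaf_size and max_trees must be >= 1")
        if self.min_split_size < 2 * self.min_leaf_size:
            raise ValueError("min_split_size must be >= 2 * min_leaf_size")
        if self.impurity != "gini":
            raise ValueError(f"unsupported impurity criterion: {self.impurity!r}")


@dataclass
class TreeNode:
    """One node of a decision tree.

    Internal nodes carry a ``(split_descriptor, split_threshold)`` test
    (``x <= threshold`` goes left) and exactly two children.  Terminal
    nodes carry the compound count ``n_total``, the binder count
    ``n_active`` and the binder ``probability = n_active / n_total``.
    """

    split_descriptor: str | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    n_total: int = 0
    n_active: int = 0
    probability: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split_descriptor is None


@dataclass
class DecisionTree:
    root: TreeNode
    used_descriptors: frozenset[str]

    def predict_proba(self, values: np.ndarray, columns: dict[str, int]) -> np.ndarray:
        """Binder probability per row of *values* (columns mapped by name)."""
        out = np.empty(values.shape[0], dtype=np.float64)
        for i in range(values.shape[0]):
            node = self.root
            while not node.is_leaf:
                j = columns[node.split_descriptor]
                node = node.left if values[i, j] <= node.split_threshold else node.right
            out[i] = node.probability
        return out


@dataclass
class DecisionForest:
    """Ordered member trees with pairwise-disjoint descriptor subsets."""

    trees: list[DecisionTree]
    training_trace: list[int]
    hyperparams: TreeParams
    descriptor_names: list[str] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def used_descriptors(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.trees:
            out |= t.used_descriptors
        return frozenset(out)

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("a forest must contain at least one tree")
        seen: set[str] = set()
        for t in self.trees:
            overlap = seen & t.used_descriptors
            if overlap:
                raise ValueError(
                    f"member trees share descriptors: {sorted(overlap)}"
                )
            seen |= t.used_descriptors


# ---------------------------------------------------------------------------
# split search


def _leaf(y: np.ndarray, smoothing: bool) -> TreeNode:
    n = int(y.size)
    a = int(y.sum())
    if smoothing:
        p = (a + 1.0) / (n + 2.0)  # Laplace
    else:
        p = a / n
    return TreeNode(n_total=n, n_active=a, probability=p)


def _best_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Best (column, threshold, score) over all midpoint candidates.

    The score of a split is ``aL(nL-aL)/nL + aR(nR-aR)/nR`` where ``n*``
    and ``a*`` are child sizes and binder counts — the weighted Gini
    impurity of the children times ``n/2``, so minimising it minimises
    weighted Gini.  All products are integers exactly representable in
    float64, which keeps tie detection exact.  Ties are broken by lower
    column index, then lower threshold.  Returns ``None`` when no
    candidate satisfies the leaf-size constraint.
    """
    n, d = X.shape
    if n < 2 * min_leaf:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]
    a = float(y.sum())
    cum = np.cumsum(ys, axis=0, dtype=np.float64)

    nL = np.arange(1, n, dtype=np.float64)[:, None]  # (n-1, 1)
    nR = float(n) - nL
    aL = cum[:-1]  # (n-1, d)
    aR = a - aL
    score = (aL * (nL - aL) * nR + aR * (nR - aR) * nL) / (nL * nR)

    valid = Xs[1:] > Xs[:-1]
    size_ok = (nL >= min_leaf) & (nR >= min_leaf)
    score = np.where(valid & size_ok, score, np.inf)

    # per-column best: argmin returns the first minimum, i.e. the lowest
    # threshold since midpoints increase with sorted position
    best_pos = np.argmin(score, axis=0)
    best_per_col = score[best_pos, np.arange(d)]
    col = int(np.argmin(best_per_col))  # first minimum -> lowest column index
    if not np.isfinite(best_per_col[col]):
        return None
    pos = int(best_pos[col])
    lo, hi = Xs[pos, col], Xs[pos + 1, col]
    threshold = lo + (hi - lo) / 2.0
    if threshold <= lo:  # guard against midpoint underflow on close values
        threshold = hi
    return col, float(threshold), float(best_per_col[col])


def _node_score(y: np.ndarray) -> float:
    n = float(y.size)
    a = float(y.sum())
    return a * (n - a) / n


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    depth: int,
    params: TreeParams,
    used: set[str],
) -> TreeNode:
    n = y.size
    a = int(y.sum())
    if (
        depth >= params.max_depth
        or a == 0
        or a == n
        or n < params.min_split_size
    ):
        return _leaf(y, params.smoothing)
    found = _best_split(X, y, params.min_leaf_size)
    if found is None:
        return _leaf(y, params.smoothing)
    col, threshold, score = found
    if not score < _node_score(y):  # no strict impurity reduction
        return _leaf(y, params.smoothing)
    mask = X[:, col] <= threshold
    node = TreeNode(split_descriptor=names[col], split_threshold=threshold)
    used.add(names[col])
    node.left = _grow(X[mask], y[mask], names, depth + 1, params, used)
    node.right = _grow(X[~mask], y[~mask], names, depth + 1, params, used)
    node.n_total = n
    node.n_active = a
    return node


def fit_tree(
    ds: LabeledDataset,
    allowed: set[str] | None = None,
    params: TreeParams = TreeParams(),
) -> DecisionTree:
    """Grow one CART tree on *ds*, splitting only on *allowed* descriptors.

    A single-class dataset yields a degenerate single-leaf tree.  Order of
    the *allowed* set does not matter: candidate columns are always
    considered in the dataset's original column order.
    """
    if not ds.is_labeled():
        raise ValueError("fit_tree requires a labeled dataset")
    names = ds.descriptor_names
    if allowed is None:
        allowed_idx = list(range(len(names)))
    else:
        if not allowed:
            raise ValueError("allowed descriptor set is empty")
        unknown = set(allowed) - set(names)
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")
        allowed_idx = [j for j, nm in enumerate(names) if nm in allowed]
    X = ds.values()[:, allowed_idx]
    y = ds.label_array()
    sub_names = [names[j] for j in allowed_idx]
    used: set[str] = set()
    root = _grow(X, y.astype(np.float64), sub_names, 0, params, used)
    return DecisionTree(root=root, used_descriptors=frozenset(used))


# ---------------------------------------------------------------------------
# forest


def _forest_errors(
    trees: list[DecisionTree], values: np.ndarray, columns: dict[str, int], y: np.ndarray
) -> int:
    probs = np.mean([t.predict_proba(values, columns) for t in trees], axis=0)
    calls = (probs > 0.5).astype(np.int64)
    return int(np.sum(calls != y))


def fit_forest(ds: LabeledDataset, params: TreeParams = TreeParams()) -> DecisionForest:
    """Fit a Decision Forest by successive trees on disjoint descriptors.

    Tree ``k+1`` is grown on the descriptors unused by trees ``1..k``.
    The first tree is always kept; each later candidate is kept only if it
    strictly reduces the forest's training misclassification count under
    the probability-averaging rule, and fitting stops at the first
    non-improving candidate, at zero training error, when the descriptor
    pool is exhausted, or at ``max_trees``.  ``training_trace`` records
    the misclassification count after each accepted tree.
    """
    if not ds.is_labeled():
        raise ValueError("fit_forest requires a labeled dataset")
    if ds.n_descriptors == 0:
        raise ValueError("dataset has no descriptors")
    names = ds.descriptor_names
    columns = {nm: j for j, nm in enumerate(names)}
    values = ds.values()
    y = ds.label_array()

    pool = set(names)
    trees: list[DecisionTree] = []
    trace: list[int] = []
    best_err: int | None = None
    while pool and len(trees) < params.max_trees:
        candidate = fit_tree(ds, allowed=pool, params=params)
        cand_err = _forest_errors(trees + [candidate], values, columns, y)
        if best_err is None:
            accept = True
        else:
            accept = cand_err < best_err
        if not accept:
            break
        trees.append(candidate)
        trace.append(cand_err)
        best_err = cand_err
        pool -= candidate.used_descriptors
        if not candidate.used_descriptors:  # degenerate leaf cannot free pool
            break
        if best_err == 0:
            break
    return DecisionForest(
        trees=trees,
        training_trace=trace,
        hyperparams=params,
        descriptor_names=names,
    )


def predict_proba(forest: DecisionForest, ds: LabeledDataset) -> np.ndarray:
    """Mean terminal-node binder probability over member trees, per compound."""
    missing = forest.used_descriptors - set(ds.descriptor_names)
    if missing:
        raise ValueError(f"dataset lacks descriptor column(s): {sorted(missing)}")
    columns = {nm: j for j, nm in enumerate(ds.descriptor_names)}
    values = ds.values()
    per_tree = np.array([t.predict_proba(values, columns) for t in forest.trees])
    return per_tree.mean(axis=0)


def classify(p: float | np.ndarray, threshold: float = 0.5) -> np.ndarray | int:
    """Binder (1) iff ``p > threshold``; the boundary itself is a non-binder."""
    arr = np.asarray(p, dtype=np.float64)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError("probability outside [0, 1]")
    calls = (arr > threshold).astype(np.int64)
    if np.isscalar(p) or arr.ndim == 0:
        return int(calls)
    return calls


# ---------------------------------------------------------------------------
# serialization: human-readable JSON, bit-exact float round trip


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {
            "leaf": True,
            "n_total": node.n_total,
            "n_active": node.n_active,
            "probability": node.probability,
        }
    return {
        "leaf": False,
        "split_descriptor": node.split_descriptor,
        "split_threshold": node.split_threshold,
        "n_total": node.n_total,
        "n_active": node.n_active,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> TreeNode:
    if d["leaf"]:
        return TreeNode(
            n_total=d["n_total"],
            n_active=d["n_active"],
            probability=d["probability"],
        )
    return TreeNode(
        split_descriptor=d["split_descriptor"],
        split_threshold=d["split_threshold"],
        n_total=d["n_total"],
        n_active=d["n_active"],
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def save_forest(forest: DecisionForest, path) -> None:
    doc = {
        "format": "erscreen-decision-forest",
        "version": 1,
        "hyperparams": {
            "max_depth": forest.hyperparams.max_depth,
            "min_leaf_size": forest.hyperparams.min_leaf_size,
            "min_split_size": forest.hyperparams.min_split_size,
            "impurity": forest.hyperparams.impurity,
            "max_trees": forest.hyperparams.max_trees,
            "smoothing": forest.hyperparams.smoothing,
            "seed": forest.hyperparams.seed,
        },
        "training_trace": forest.training_trace,
        "descriptor_names": forest.descriptor_names,
        "trees": [
            {
                "used_descriptors": sorted(t.used_descriptors),
                "root": _node_to_dict(t.root),
            }
            for t in forest.trees
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_forest(path) -> DecisionForest:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "erscreen-decision-forest":
        raise ValueError(f"{path}: not a serialized decision forest")
    params = TreeParams(**doc["hyperparams"])
    trees = [
        DecisionTree(
            root=_node_from_dict(t["root"]),
            used_descriptors=frozenset(t["used_descriptors"]),
        )
        for t in doc["trees"]
    ]
    return DecisionForest(
        trees=trees,
        training_trace=list(doc["training_trace"]),
        hyperparams=params,
        descriptor_names=list(doc["descriptor_names"]),
    )
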