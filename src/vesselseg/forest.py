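"""Random decision forest with two-threshold interval split nodes.

Each internal node routes a structure x by the binary test
``tau1 > f(x|w) > tau2`` on a single feature: samples strictly inside the
interval go to the left child, all others to the right. An interval test is
strictly more expressive per node than the usual single threshold — a class
occupying the middle band of a feature is separable in one node, which a
single threshold cannot do.

Trees are grown on independent bootstrap replicas of the training set; at
each node only a random subset of the six features is examined, the best
interval (by Shannon information gain, in bits) per feature is found over
midpoint candidate thresholds, and growth stops when the gain becomes
insignificant, the node is pure or too small, or the depth cap is reached.
The forest predicts by the statistical mode of the tree votes. All
tie-breaks (leaf label, forest vote) resolve toward class N, the
conservative non-vessel call: false positives are the primary error to
avoid.

Classes: 'M' = microvessel, 'N' = everything else (arteries, veins, neurons,
background clutter).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .structures import FEATURE_NAMES

CLASS_M = "M"
CLASS_N = "N"
_CLASSES = (CLASS_M, CLASS_N)

MODEL_FORMAT_VERSION = 1


def _class_entropy(n_m: float, n_n: float) -> float:
    """Shannon entropy (bits) of a two-class multiset given class counts."""
    n = n_m + n_n
    if n == 0:
        return 0.0
    h = 0.0
    for c in (n_m, n_n):
        if c > 0:
            p = c / n
            h -= p * np.log2(p)
    return float(h)


def information_gain(parent_labels, left_labels, right_labels) -> float:
    """Information gain of splitting ``parent`` into ``left`` | ``right``.

    ``H(P) - |L|/|P| H(L) - |R|/|P| H(R)`` with H the Shannon entropy of the
    class distribution, in bits. The children must partition the parent as
    multisets. Always >= 0; zero iff the split leaves the class proportions
    unchanged in both children.
    """
    parent = Counter(parent_labels)
    left = Counter(left_labels)
    right = Counter(right_labels)
    if not parent:
        raise ValueError("parent multiset is empty")
    if left + right != parent:
        raise ValueError("left and right do not partition the parent multiset")
    n = sum(parent.values())
    nl = sum(left.values())
    nr = sum(right.values())
    hp = _class_entropy(parent[CLASS_M], parent[CLASS_N])
    hl = _class_entropy(left[CLASS_M], left[CLASS_N])
    hr = _class_entropy(right[CLASS_M], right[CLASS_N])
    return max(0.0, hp - (nl / n) * hl - (nr / n) * hr)


class SplitResult(NamedTuple):
    tau1: float
    tau2: float
    gain: float
    degenerate: bool


def _candidate_thresholds(values: np.ndarray, candidate_grid: int) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values, capped at
    ``candidate_grid`` quantile midpoints when there are too many."""
    distinct = np.unique(values)
    if distinct.size > candidate_grid + 1:
        distinct = np.unique(np.quantile(distinct, np.linspace(0, 1, candidate_grid + 1)))
    return (distinct[:-1] + distinct[1:]) / 2.0


def best_interval_split(
    values, labels, candidate_grid: int = 32
) -> SplitResult:
    """Exhaustive search for the best interval test on one feature.

    Returns the (tau1, tau2) pair with tau1 > tau2 maximizing information
    gain, where samples with tau2 < v < tau1 go left and the rest right.
    Ties break toward the wider interval, then the lower tau2 — fully
    deterministic. All-identical values yield a degenerate zero-gain result.
    """
    values = np.asarray(values, dtype=np.float64)
    y = np.asarray([1 if l == CLASS_M else 0 for l in labels], dtype=np.int64)
    if values.shape[0] != y.shape[0]:
        raise ValueError("values and labels differ in length")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    cand = _candidate_thresholds(values, candidate_grid)
    if cand.size < 2:
        return SplitResult(np.nan, np.nan, 0.0, True)

    order = np.argsort(values, kind="stable")
    sv = values[order]
    sy = y[order]
    # counts of samples (and class-M samples) strictly below each candidate
    n_lt = np.searchsorted(sv, cand, side="left").astype(np.float64)
    m_cum = np.concatenate(([0.0], np.cumsum(sy)))
    m_lt = m_cum[np.searchsorted(sv, cand, side="left")]

    n = float(values.shape[0])
    n_m = float(y.sum())
    hp = _class_entropy(n_m, n - n_m)

    # pairwise: tau2 = cand[a], tau1 = cand[b], a < b
    n_in = n_lt[None, :] - n_lt[:, None]  # [a, b]
    m_in = m_lt[None, :] - m_lt[:, None]
    valid = np.triu(np.ones_like(n_in, dtype=bool), k=1)

    def h2(nm, nn):
        tot = nm + nn
        with np.errstate(divide="ignore", invalid="ignore"):
            pm = np.where(tot > 0, nm / np.maximum(tot, 1e-300), 0.0)
            pn = np.where(tot > 0, nn / np.maximum(tot, 1e-300), 0.0)
            out = -(
                np.where(pm > 0, pm * np.log2(np.maximum(pm, 1e-300)), 0.0)
                + np.where(pn > 0, pn * np.log2(np.maximum(pn, 1e-300)), 0.0)
            )
        return out

    n_out = n - n_in
    m_out = n_m - m_in
    h_in = h2(m_in, n_in - m_in)
    h_out = h2(m_out, n_out - m_out)
    gain = hp - (n_in / n) * h_in - (n_out / n) * h_out
    gain = np.where(valid, np.maximum(gain, 0.0), -1.0)

    best = gain.max()
    if best <= 0.0:
        # no informative interval; still return a deterministic pair
        return SplitResult(float(cand[-1]), float(cand[0]), 0.0, True)
    # tie-break: widest interval, then lowest tau2
    near = np.argwhere(gain >= best - 1e-12)
    widths = cand[near[:, 1]] - cand[near[:, 0]]
    key = np.lexsort((cand[near[:, 0]], -widths))  # primary: -width, secondary: tau2
    a, b = near[key[0]]
    return SplitResult(float(cand[b]), float(cand[a]), float(best), False)


@dataclass
class SplitNode:
    feature_index: int
    tau1: float
    tau2: float
    left: "SplitNode | Leaf"
    right: "SplitNode | Leaf"

    def __post_init__(self) -> None:
        if not self.tau1 > self.tau2:
            raise ValueError("split node requires tau1 > tau2")


@dataclass
class Leaf:
    label: str
    n_m: int = 0
    n_n: int = 0


@dataclass
class DecisionTree:
    root: "SplitNode | Leaf"

    def predict_one(self, x: np.ndarray) -> str:
        node = self.root
        while isinstance(node, SplitNode):
            v = x[node.feature_index]
            node = node.left if (node.tau2 < v < node.tau1) else node.right
        return node.label


@dataclass
class ForestModel:
    trees: list[DecisionTree]
    feature_names: tuple[str, ...] = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    subset_size: int,
    gain_epsilon: float,
    min_samples: int,
    max_depth: int,
    candidate_grid: int,
    depth: int = 0,
):
    n_m = int((y == 1).sum())
    n_n = int(y.shape[0] - n_m)

    def leaf() -> Leaf:
        # majority class; tie resolves to N (conservative non-vessel call)
        return Leaf(label=CLASS_M if n_m > n_n else CLASS_N, n_m=n_m, n_n=n_n)

    if (
        y.shape[0] < min_samples
        or depth >= max_depth
        or n_m == 0
        or n_n == 0
    ):
        return leaf()

    feats = np.sort(rng.choice(X.shape[1], size=subset_size, replace=False))
    labels = np.where(y == 1, CLASS_M, CLASS_N)
    best = None
    for fi in feats:
        res = best_interval_split(X[:, fi], labels, candidate_grid)
        if res.degenerate:
            continue
        if best is None or res.gain > best[1].gain + 1e-12:
            best = (int(fi), res)
    if best is None or best[1].gain < gain_epsilon:
        return leaf()
    fi, res = best
    inside = (X[:, fi] > res.tau2) & (X[:, fi] < res.tau1)
    if not inside.any() or inside.all():
        return leaf()
    left = _grow_tree(
        X[inside], y[inside], rng, subset_size, gain_epsilon, min_samples,
        max_depth, candidate_grid, depth + 1,
    )
    right = _grow_tree(
        X[~inside], y[~inside], rng, subset_size, gain_epsilon, min_samples,
        max_depth, candidate_grid, depth + 1,
    )
    return SplitNode(feature_index=fi, tau1=res.tau1, tau2=res.tau2, left=left, right=right)


def train_forest(
    X,
    y,
    n_trees: int = 64,
    subset_size: int = 3,
    seed: int = 0,
    gain_epsilon: float = 1e-6,
    min_samples: int = 2,
    max_depth: int = 16,
    candidate_grid: int = 32,
    bootstrap: bool = True,
) -> ForestModel:
    """Train the forest on (n, 6) feature rows with labels in {'M', 'N'}.

    Records are first sorted canonically (lexicographically by features, then
    label) so training is invariant to the order the caller supplies them in;
    all randomness then flows from ``seed``. Refuses single-class input.
    Out-of-bag accuracy over the training set is stored in ``metadata``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    yy = np.asarray([1 if l == CLASS_M else 0 for l in y], dtype=np.int64)
    if X.shape[0] != yy.shape[0]:
        raise ValueError("X and y differ in length")
    if X.shape[0] < 2 or len(set(yy.tolist())) < 2:
        raise ValueError("training requires at least 2 records with both classes present")
    if not (1 <= subset_size <= X.shape[1]):
        raise ValueError("subset_size must be in [1, n_features]")

    # canonical ordering -> record-order invariance
    order = np.lexsort(tuple(X[:, j] for j in reversed(range(X.shape[1]))) + (yy,))
    X = X[order]
    yy = yy[order]
    n = X.shape[0]

    rng = np.random.default_rng(seed)
    trees: list[DecisionTree] = []
    oob_votes_m = np.zeros(n, dtype=np.int64)
    oob_votes_n = np.zeros(n, dtype=np.int64)
    for _ in range(n_trees):
        if bootstrap:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.arange(n)
        tree = DecisionTree(
            root=_grow_tree(
                X[idx], yy[idx], rng, subset_size, gain_epsilon, min_samples,
                max_depth, candidate_grid,
            )
        )
        trees.append(tree)
        if bootstrap:
            oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
            for i in oob:
                if tree.predict_one(X[i]) == CLASS_M:
                    oob_votes_m[i] += 1
                else:
                    oob_votes_n[i] += 1

    covered = (oob_votes_m + oob_votes_n) > 0
    oob_acc = None
    if bootstrap and covered.any():
        pred_m = oob_votes_m > oob_votes_n  # tie -> N
        oob_acc = float((pred_m[covered] == (yy[covered] == 1)).mean())
    names = (
        FEATURE_NAMES
        if X.shape[1] == len(FEATURE_NAMES)
        else tuple(f"f{j}" for j in range(X.shape[1]))
    )
    return ForestModel(
        trees=trees,
        feature_names=names,
        metadata={
            "seed": int(seed),
            "n_trees": int(n_trees),
            "subset_size": int(subset_size),
            "gain_epsilon": gain_epsilon,
            "min_samples": int(min_samples),
            "max_depth": int(max_depth),
            "candidate_grid": int(candidate_grid),
            "bootstrap": bool(bootstrap),
            "n_training_records": int(n),
            "oob_accuracy": oob_acc,
        },
    )


def predict(model: ForestModel, x) -> str:
    """Forest prediction for one feature vector: mode of tree votes, tie -> N."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (len(model.feature_names),):
        raise ValueError(
            f"expected feature vector of length {len(model.feature_names)}, got {x.shape}"
        )
    votes_m = sum(1 for t in model.trees if t.predict_one(x) == CLASS_M)
    return CLASS_M if votes_m > model.n_trees - votes_m else CLASS_N


def predict_batch(model: ForestModel, X) -> list[str]:
    X = np.asarray(X, dtype=np.float64)
    return [predict(model, row) for row in X]


# ---------------------------------------------------------------------------
# serialization (versioned JSON)

def _node_to_dict(node) -> dict:
    if isinstance(node, Leaf):
        return {"leaf": node.label, "n_m": node.n_m, "n_n": node.n_n}
    return {
        "feature": node.feature_index,
        "tau1": node.tau1,
        "tau2": node.tau2,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict):
    if "leaf" in d:
        return Leaf(label=d["leaf"], n_m=d.get("n_m", 0), n_n=d.get("n_n", 0))
    return SplitNode(
        feature_index=int(d["feature"]),
        tau1=float(d["tau1"]),
        tau2=float(d["tau2"]),
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def model_to_json(model: ForestModel) -> str:
    return json.dumps(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_names": list(model.feature_names),
            "metadata": model.metadata,
            "trees": [_node_to_dict(t.root) for t in model.trees],
        },
        indent=1,
    )


def model_from_json(text: str) -> ForestModel:
    d = json.loads(text)
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {d.get('format_version')}")
    return ForestModel(
        trees=[DecisionTree(root=_node_from_dict(t)) for t in d["trees"]],
        feature_names=tuple(d["feature_names"]),
        metadata=d.get("metadata", {}),
    )


def save_model(model: ForestModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(model_to_json(model))


def load_model(path) -> ForestModel:
    with open(path) as fh:
        return model_from_json(fh.read())
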