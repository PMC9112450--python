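"""Axis-aligned decision trees and majority-vote random forests.

Trees are stored in an explicit node structure so that they can be rewritten
by the rule-minimization pass (:mod:`akiforest.boolmin`) and serialized to a
plain JSON document. Fitting delegates to scikit-learn's CART implementation
(Gini impurity, bootstrap resampling, sqrt-feature subsetting per split,
best-first growth under a leaf-count cap); the fitted sklearn trees are then
extracted into this structure and sklearn plays no further role.

Prediction convention: an internal node tests ``feature <= threshold``; the
left child is the *true* branch. The forest predicts by unweighted majority
vote with ties broken toward the positive (AKI) class — the clinically
conservative choice — so the reported confidence (vote fraction for the
winning class) always lies in [0.5, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .records import LabeledDataset

POSITIVE_LABEL = 1


@dataclass(frozen=True)
class HyperParams:
    """Forest hyper-parameters: tree depth, leaf occupancy, leaf count, size.

    depth
        maximum depth of each tree (root-to-leaf edges), >= 1.
    MSPL
        minimal number of training samples per leaf, >= 1.
    LC
        maximum leaf count per tree (best-first growth stops there), >= 2.
    n
        number of trees in the forest, >= 1.
    """

    depth: int = 5
    MSPL: int = 1
    LC: int = 32
    n: int = 100

    def __post_init__(self) -> None:
        for name in ("depth", "MSPL", "LC", "n"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.LC < 2:
            raise ValueError(f"LC must be >= 2, got {self.LC}")
        if self.LC > 2 ** self.depth:
            raise ValueError(
                f"LC={self.LC} unreachable at depth {self.depth} (max {2 ** self.depth} leaves)"
            )


@dataclass(frozen=True)
class Leaf:
    label: int
    counts: tuple[int, int] | None = None  # (n_negative, n_positive) in training

    @property
    def is_leaf(self) -> bool:
        return True


@dataclass(frozen=True)
class Split:
    feature: str
    threshold: float
    left: "Node"   # feature <= threshold
    right: "Node"  # feature >  threshold

    @property
    def is_leaf(self) -> bool:
        return False


Node = Leaf | Split


@dataclass(frozen=True)
class DecisionTreeModel:
    root: Node
    feature_names: tuple[str, ...]

    def predict_record(self, record: Mapping[str, float]) -> int:
        node = self.root
        while not node.is_leaf:
            try:
                value = record[node.feature]
            except KeyError:
                raise KeyError(
                    f"record is missing feature {node.feature!r} required by the model"
                ) from None
            node = node.left if value <= node.threshold else node.right
        return node.label

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        index = {f: j for j, f in enumerate(self.feature_names)}
        out = np.empty(len(X), dtype=int)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[index[node.feature]] <= node.threshold else node.right
            out[i] = node.label
        return out

    def leaves(self) -> Iterator[Leaf]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend((node.right, node.left))

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    @property
    def depth(self) -> int:
        def d(node: Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def thresholds(self) -> dict[str, list[float]]:
        """Distinct split thresholds per feature, sorted ascending."""
        found: dict[str, set[float]] = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                found.setdefault(node.feature, set()).add(node.threshold)
                stack.extend((node.right, node.left))
        return {f: sorted(ts) for f, ts in found.items()}


@dataclass(frozen=True)
class ForestModel:
    trees: tuple[DecisionTreeModel, ...]
    hyper: HyperParams
    seed: int
    feature_names: tuple[str, ...]
    pruned: bool = False

    def __post_init__(self) -> None:
        if len(self.trees) != self.hyper.n:
            raise ValueError(f"forest holds {len(self.trees)} trees, hyper.n={self.hyper.n}")

    def predict_record(self, record: Mapping[str, float]) -> tuple[int, float]:
        """Majority-vote label and vote-fraction confidence for one record."""
        votes = sum(t.predict_record(record) for t in self.trees)
        n = len(self.trees)
        positive_frac = votes / n
        if positive_frac >= 0.5:  # tie -> AKI
            return POSITIVE_LABEL, positive_frac
        return 1 - POSITIVE_LABEL, 1.0 - positive_frac

    def vote_fraction(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting AKI per row — the model's risk score."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros(len(X), dtype=float)
        for tree in self.trees:
            votes += tree.predict(X)
        return votes / len(self.trees)

    def predict_batch(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels, positive-class scores) for a feature matrix."""
        score = self.vote_fraction(X)
        labels = (score >= 0.5).astype(int)  # tie -> AKI
        return labels, score

    def with_trees(self, trees: Sequence[DecisionTreeModel], pruned: bool) -> "ForestModel":
        return replace(self, trees=tuple(trees), pruned=pruned)


def fit_forest(
    data: LabeledDataset,
    hyper: HyperParams,
    seed: int,
    max_features: str | int | None = "sqrt",
) -> ForestModel:
    """Fit a random forest honoring the depth/MSPL/LC/n constraints.

    Each tree is grown CART-style on a bootstrap resample with a random
    sqrt-sized feature subset considered at every split (``max_features``
    overrides the subset size; ``None`` considers every feature).
    Deterministic for a given seed. Raises on empty or single-class data.
    """
    if len(data) == 0:
        raise ValueError("cannot fit a forest on an empty dataset")
    classes = np.unique(data.y)
    if len(classes) < 2:
        raise ValueError(
            f"degenerate label distribution: only class {classes.tolist()} present; "
            "both AKI and non-AKI records are required"
        )
    clf = RandomForestClassifier(
        n_estimators=hyper.n,
        criterion="gini",
        max_depth=hyper.depth,
        min_samples_leaf=hyper.MSPL,
        max_leaf_nodes=hyper.LC,
        max_features=max_features,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(data.X, data.y)
    trees = tuple(
        _extract_tree(est.tree_, data.feature_names) for est in clf.estimators_
    )
    return ForestModel(
        trees=trees,
        hyper=hyper,
        seed=int(seed),
        feature_names=data.feature_names,
    )


def _extract_tree(sk_tree, feature_names: Sequence[str]) -> DecisionTreeModel:
    def build(i: int) -> Node:
        if sk_tree.children_left[i] == -1:
            counts = sk_tree.value[i][0] * sk_tree.weighted_n_node_samples[i]
            counts = np.rint(counts).astype(int)
            n_neg = int(counts[0]) if len(counts) > 0 else 0
            n_pos = int(counts[1]) if len(counts) > 1 else 0
            # tie in class counts -> positive, matching the vote tie rule
            label = POSITIVE_LABEL if n_pos >= n_neg else 1 - POSITIVE_LABEL
            return Leaf(label=label, counts=(n_neg, n_pos))
        return Split(
            feature=feature_names[sk_tree.feature[i]],
            threshold=float(sk_tree.threshold[i]),
            left=build(sk_tree.children_left[i]),
            right=build(sk_tree.children_right[i]),
        )

    return DecisionTreeModel(root=build(0), feature_names=tuple(feature_names))


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _node_to_obj(node: Node) -> dict:
    if node.is_leaf:
        obj: dict = {"leaf": {"label": int(node.label)}}
        if node.counts is not None:
            obj["leaf"]["counts"] = [int(c) for c in node.counts]
        return obj
    return {
        "node": {
            "feature": node.feature,
            "threshold": node.threshold,
            "left": _node_to_obj(node.left),
            "right": _node_to_obj(node.right),
        }
    }


def _node_from_obj(obj: dict, path: str) -> Node:
    if not isinstance(obj, dict) or len(obj) != 1:
        raise ValueError(f"malformed node at {path}: expected a 'leaf' or 'node' object")
    if "leaf" in obj:
        leaf = obj["leaf"]
        if "label" not in leaf:
            raise ValueError(f"malformed leaf at {path}: missing 'label'")
        counts = leaf.get("counts")
        return Leaf(
            label=int(leaf["label"]),
            counts=tuple(int(c) for c in counts) if counts is not None else None,
        )
    if "node" in obj:
        node = obj["node"]
        for key in ("feature", "threshold", "left", "right"):
            if key not in node:
                raise ValueError(f"malformed split at {path}: missing {key!r}")
        return Split(
            feature=str(node["feature"]),
            threshold=float(node["threshold"]),
            left=_node_from_obj(node["left"], path + ".left"),
            right=_node_from_obj(node["right"], path + ".right"),
        )
    raise ValueError(f"malformed node at {path}: keys {sorted(obj)}")


def serialize_model(model: ForestModel) -> str:
    doc = {
        "hyper": {
            "depth": model.hyper.depth,
            "MSPL": model.hyper.MSPL,
            "LC": model.hyper.LC,
            "n": model.hyper.n,
        },
        "seed": model.seed,
        "feature_names": list(model.feature_names),
        "pruned": model.pruned,
        "trees": [_node_to_obj(t.root) for t in model.trees],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def deserialize_model(text: str) -> ForestModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"parse error in model document at line {exc.lineno}, "
                         f"column {exc.colno}: {exc.msg}") from exc
    for key in ("hyper", "seed", "feature_names", "trees"):
        if key not in doc:
            raise ValueError(f"model document missing top-level key {key!r}")
    hyper = HyperParams(**{k: int(v) for k, v in doc["hyper"].items()})
    feature_names = tuple(doc["feature_names"])
    trees = tuple(
        DecisionTreeModel(root=_node_from_obj(obj, f"trees[{i}]"), feature_names=feature_names)
        for i, obj in enumerate(doc["trees"])
    )
    return ForestModel(
        trees=trees,
        hyper=hyper,
        seed=int(doc["seed"]),
        feature_names=feature_names,
        pruned=bool(doc.get("pruned", False)),
    )
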