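"""Binary classification trees over binary hydrogen-bond features.

Greedy CART with the Gini diversity index labels each trajectory frame's
damage class from the presence/absence of residue-pair hydrogen bonds.
Because features are binary, every split is a presence test ("is bond f
formed?"); the tree is grown to purity and then simplified by *level
pruning*: removing k levels collapses every node deeper than (depth − k)
into a leaf carrying the merged class counts of its subtree.  Leaf class
probabilities are exactly [frames of class c reaching the leaf] / [all
frames reaching the leaf], and resubstitution loss is the fraction of
training frames the pruned tree mislabels — the quantities a practitioner
reads off the prune curve to pick an interpretable two- or three-bond motif.

Depth counts split levels: a lone leaf has depth 0, a root split with leaf
children depth 1, and the two-bond flow-chart tree depth 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hbonds import FeatureMatrix

__all__ = [
    "TreeNode",
    "ClassificationTree",
    "fit_tree",
    "prune",
    "loss",
    "predict",
    "leaf_probabilities",
    "prune_curve",
    "export_tree",
    "import_tree",
]


class SchemaError(ValueError):
    """Feature schema of the data does not match the tree's."""


@dataclass
class TreeNode:
    """One node: a leaf (``feature is None``) or a presence split whose
    ``absent``/``present`` children take the frames with feature 0/1."""

    counts: np.ndarray                 # (n_classes,) training frames reaching this node
    feature: int | None = None
    absent: "TreeNode | None" = None
    present: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty node has undefined class probabilities")
        return self.counts / self.total

    @property
    def predicted(self) -> int:
        return int(np.argmax(self.counts))  # argmax ties -> lowest class index

    @property
    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.absent.depth, self.present.depth)


@dataclass
class ClassificationTree:
    root: TreeNode
    classes: list[str]
    feature_names: list[str] = field(default_factory=list)

    @property
    def depth(self) -> int:
        """Number of split levels (0 for a single-leaf tree)."""
        return self.root.depth

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.present, node.absent])
        return out

    def split_features(self) -> list[int]:
        """Distinct feature indices used by splits, in first-use (BFS) order."""
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            if not node.is_leaf:
                if node.feature not in out:
                    out.append(node.feature)
                queue.extend([node.absent, node.present])
        return out


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(X: np.ndarray, onehot: np.ndarray) -> int | None:
    """Feature index minimising weighted child Gini, or None if no split
    strictly improves on the parent.  Ties break to the lowest index because
    the scan keeps the first strict minimum."""
    n = X.shape[0]
    counts = onehot.sum(axis=0)
    parent = _gini(counts)
    present = X.T.astype(np.float64) @ onehot          # (F, C)
    absent = counts[None, :] - present
    n_pres = present.sum(axis=1)
    n_abs = n - n_pres
    with np.errstate(invalid="ignore", divide="ignore"):
        g_pres = 1.0 - np.sum((present / np.maximum(n_pres, 1)[:, None]) ** 2, axis=1)
        g_abs = 1.0 - np.sum((absent / np.maximum(n_abs, 1)[:, None]) ** 2, axis=1)
    weighted = (n_pres * g_pres + n_abs * g_abs) / n
    # a split with an empty side reproduces the parent impurity exactly
    weighted = np.where((n_pres == 0) | (n_abs == 0), parent, weighted)
    best = None
    best_val = parent - 1e-12
    for j in range(X.shape[1]):
        if weighted[j] < best_val:
            best, best_val = j, weighted[j]
    return best


def fit_tree(fm: FeatureMatrix) -> ClassificationTree:
    """Grow the full tree by greedy Gini partitioning.

    Growth stops at pure nodes or when no presence split strictly reduces
    the weighted impurity (e.g. identical feature rows with mixed labels).
    A single-class input yields a lone leaf with a warning.
    """
    classes = fm.class_names
    if fm.n_features < 1:
        raise ValueError("need >= 1 feature")
    if len(classes) < 2:
        warnings.warn("single-class input: returning a degenerate one-leaf tree")
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.asarray([class_index[l] for l in fm.labels], dtype=np.intp)
    onehot_full = np.eye(len(classes))[y]
    X = fm.matrix.astype(bool)

    def build(idx: np.ndarray) -> TreeNode:
        onehot = onehot_full[idx]
        counts = onehot.sum(axis=0).astype(np.int64)
        node = TreeNode(counts=counts)
        if np.count_nonzero(counts) <= 1:
            return node
        j = _best_split(X[idx], onehot)
        if j is None:
            return node
        mask = X[idx, j]
        node.feature = j
        node.present = build(idx[mask])
        node.absent = build(idx[~mask])
        return node

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10_000))
    try:
        root = build(np.arange(fm.n_frames))
    finally:
        sys.setrecursionlimit(old_limit)
    return ClassificationTree(root=root, classes=classes, feature_names=list(fm.descriptors))


def _collapse_below(node: TreeNode, remaining: int) -> TreeNode:
    if node.is_leaf or remaining == 0:
        return TreeNode(counts=node.counts.copy())
    return TreeNode(
        counts=node.counts.copy(),
        feature=node.feature,
        absent=_collapse_below(node.absent, remaining - 1),
        present=_collapse_below(node.present, remaining - 1),
    )


def prune(tree: ClassificationTree, levels_removed: int) -> ClassificationTree:
    """Remove ``levels_removed`` split levels from the bottom.

    Every node deeper than (depth − levels_removed) split levels collapses
    into a leaf carrying the merged counts of its subtree; the leaf then
    predicts the subtree-majority class, the collapse order with least loss.
    ``levels_removed == depth`` leaves the majority-baseline root leaf.
    """
    if not 0 <= levels_removed <= tree.depth:
        raise ValueError(
            f"levels_removed must lie in [0, {tree.depth}], got {levels_removed}"
        )
    if levels_removed == 0:
        return tree
    root = _collapse_below(tree.root, tree.depth - levels_removed)
    return ClassificationTree(root=root, classes=tree.classes, feature_names=tree.feature_names)


def _apply(tree: ClassificationTree, X: np.ndarray) -> np.ndarray:
    """Leaf node per row of the binary feature matrix."""
    n = X.shape[0]
    out = np.empty(n, dtype=object)
    stack = [(tree.root, np.arange(n))]
    while stack:
        node, idx = stack.pop()
        if node.is_leaf:
            out[idx] = node
            continue
        if node.feature >= X.shape[1]:
            raise SchemaError(
                f"tree splits on feature {node.feature} but data has {X.shape[1]} columns"
            )
        mask = X[idx, node.feature].astype(bool)
        stack.append((node.present, idx[mask]))
        stack.append((node.absent, idx[~mask]))
    return out


def predict(tree: ClassificationTree, features: np.ndarray):
    """Predicted class label(s) and probability row(s) for feature vector(s)."""
    X = np.atleast_2d(np.asarray(features))
    if X.shape[1] != len(tree.feature_names):
        raise SchemaError(
            f"feature vector length {X.shape[1]} != tree schema {len(tree.feature_names)}"
        )
    leaves = _apply(tree, X)
    labels = np.asarray([tree.classes[leaf.predicted] for leaf in leaves], dtype=object)
    probs = np.stack([leaf.probabilities for leaf in leaves])
    if np.asarray(features).ndim == 1:
        return labels[0], probs[0]
    return labels, probs


def loss(tree: ClassificationTree, fm: FeatureMatrix) -> float:
    """Fraction of frames whose predicted class differs from the label."""
    if fm.descriptors != tree.feature_names:
        raise SchemaError("feature matrix schema differs from the tree's")
    labels, _ = predict(tree, fm.matrix)
    return float(np.mean(labels != fm.labels))


def leaf_probabilities(tree: ClassificationTree) -> pd.DataFrame:
    """Per-leaf table: class frame counts, estimated probabilities
    (count ratio), predicted class, and the split path that reaches it."""
    rows = []

    def walk(node: TreeNode, path: list[str]) -> None:
        if node.is_leaf:
            row = {"path": " & ".join(path) if path else "(root)"}
            for c, cnt in zip(tree.classes, node.counts):
                row[f"n_{c}"] = int(cnt)
            for c, p in zip(tree.classes, node.probabilities):
                row[f"p_{c}"] = float(p)
            row["predicted"] = tree.classes[node.predicted]
            rows.append(row)
            return
        name = tree.feature_names[node.feature]
        walk(node.absent, path + [f"not {name}"])
        walk(node.present, path + [name])

    walk(tree.root, [])
    return pd.DataFrame(rows)


def prune_curve(tree: ClassificationTree, fm: FeatureMatrix) -> pd.DataFrame:
    """Resubstitution loss at every pruning level, 0 .. depth.

    Row 0 is the full tree; the last row is the root leaf, whose loss is the
    majority-class baseline 1 − max class frequency.
    """
    rows = [
        {"levels_removed": k, "depth": tree.depth - k, "loss": loss(prune(tree, k), fm)}
        for k in range(tree.depth + 1)
    ]
    return pd.DataFrame(rows)


def _node_to_dict(node: TreeNode, feature_names: list[str]) -> dict:
    d: dict = {"counts": [int(c) for c in node.counts]}
    if not node.is_leaf:
        d["feature"] = int(node.feature)
        d["feature_name"] = feature_names[node.feature]
        d["absent"] = _node_to_dict(node.absent, feature_names)
        d["present"] = _node_to_dict(node.present, feature_names)
    else:
        d["probabilities"] = [float(p) for p in node.probabilities]
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(counts=np.asarray(d["counts"], dtype=np.int64))
    if "feature" in d:
        node.feature = int(d["feature"])
        node.absent = _node_from_dict(d["absent"])
        node.present = _node_from_dict(d["present"])
    return node


def export_tree(tree: ClassificationTree) -> str:
    """Lossless JSON document (stable key order) for the fitted tree."""
    doc = {
        "classes": tree.classes,
        "feature_names": tree.feature_names,
        "depth": tree.depth,
        "root": _node_to_dict(tree.root, tree.feature_names),
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def import_tree(doc: str) -> ClassificationTree:
    d = json.loads(doc)
    return ClassificationTree(
        root=_node_from_dict(d["root"]),
        classes=list(d["classes"]),
        feature_names=list(d["feature_names"]),
    )
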