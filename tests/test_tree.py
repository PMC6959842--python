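"""CART fitting, count-ratio leaf probabilities, level pruning and loss."""

import itertools
import json
from fractions import Fraction

import numpy as np
import pytest

from mdworkbench.hbonds import FeatureMatrix
from mdworkbench.synthetic import HBondPlantSpec, gen_hbond_matrix
from mdworkbench import tree as dt


def fm_from(matrix, labels, descriptors=None):
    matrix = np.asarray(matrix, dtype=np.uint8)
    if descriptors is None:
        descriptors = [f"b{j}" for j in range(matrix.shape[1])]
    return FeatureMatrix(matrix=matrix, descriptors=descriptors,
                         labels=np.asarray(labels, dtype=object))


def exact_gini_split(matrix, labels):
    """Exhaustive-enumeration oracle in exact rational arithmetic.

    Returns (best feature index or None, exact weighted impurity), with
    lowest-index tie-breaking; None when no split strictly improves.
    """
    classes = sorted(set(labels))
    n = len(labels)

    def gini(counts):
        total = sum(counts)
        if total == 0:
            return Fraction(0)
        return 1 - sum(Fraction(c, total) ** 2 for c in counts)

    n_features = len(matrix[0]) if n else 0
    parent_counts = [labels.count(c) for c in classes]
    parent = gini(parent_counts)
    best, best_val = None, parent
    for j in range(n_features):
        pres = [labels[i] for i in range(n) if matrix[i][j]]
        absn = [labels[i] for i in range(n) if not matrix[i][j]]
        if not pres or not absn:
            continue
        val = (
            Fraction(len(pres), n) * gini([pres.count(c) for c in classes])
            + Fraction(len(absn), n) * gini([absn.count(c) for c in classes])
        )
        if val < best_val:
            best, best_val = j, val
    return best, best_val


class TestFit:
    def test_perfect_separator_used_at_root(self):
        fm = fm_from([[1, 0], [1, 1], [0, 0], [0, 1]], ["A", "A", "B", "B"])
        t = dt.fit_tree(fm)
        assert t.root.feature == 0
        assert dt.loss(t, fm) == 0.0

    def test_constant_features_give_majority_leaf(self):
        fm = fm_from([[1], [1], [1]], ["A", "A", "B"])
        t = dt.fit_tree(fm)
        assert t.root.is_leaf
        assert t.classes[t.root.predicted] == "A"

    def test_single_class_warns_and_returns_leaf(self):
        fm = fm_from([[0], [1]], ["A", "A"])
        with pytest.warns(UserWarning):
            t = dt.fit_tree(fm)
        assert t.root.is_leaf

    @pytest.mark.parametrize("seed", range(30))
    def test_root_split_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, f = int(rng.integers(20, 200)), int(rng.integers(2, 9))
        matrix = (rng.random((n, f)) < rng.random(f)).astype(np.uint8)
        labels = [str(c) for c in rng.integers(0, 3, size=n)]
        t = dt.fit_tree(fm_from(matrix, labels))
        oracle_feat, oracle_val = exact_gini_split(matrix.tolist(), labels)
        if t.root.is_leaf:
            assert oracle_feat is None
        else:
            # the chosen feature must achieve the exact optimal impurity
            _, chosen_val = exact_gini_split(
                matrix[:, [t.root.feature]].tolist(), labels
            )
            assert chosen_val == oracle_val

    def test_lowest_index_tie_break(self):
        # duplicated feature: identical impurity, index 0 must win
        fm = fm_from([[1, 1], [1, 1], [0, 0], [0, 0]], ["A", "A", "B", "B"])
        t = dt.fit_tree(fm)
        assert t.root.feature == 0

    def test_sklearn_cross_check_on_separable_data(self):
        """Independent CART implementation agrees on training predictions."""
        from sklearn.tree import DecisionTreeClassifier

        spec = HBondPlantSpec.default(n_frames=300, seed=8)
        fm, _ = gen_hbond_matrix(spec)
        ours = dt.fit_tree(fm)
        sk = DecisionTreeClassifier(criterion="gini", random_state=0).fit(
            fm.matrix, fm.labels.astype(str)
        )
        ours_acc = 1 - dt.loss(ours, fm)
        sk_acc = sk.score(fm.matrix, fm.labels.astype(str))
        assert ours_acc == pytest.approx(sk_acc, abs=0.01)

    def test_child_impurity_never_exceeds_parent(self):
        spec = HBondPlantSpec.default(n_frames=200, seed=3)
        fm, _ = gen_hbond_matrix(spec)
        t = dt.fit_tree(fm)

        def gini(counts):
            n = counts.sum()
            return 1 - ((counts / n) ** 2).sum() if n else 0.0

        stack = [t.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                continue
            n = node.total
            weighted = (
                node.absent.total * gini(node.absent.counts)
                + node.present.total * gini(node.present.counts)
            ) / n
            assert weighted <= gini(node.counts) + 1e-12
            stack.extend([node.absent, node.present])


class TestLeafProbabilities:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((3, 1, 0), (0.75, 0.25, 0.0)),
            ((10, 0, 0), (1.0, 0.0, 0.0)),
            ((71, 3, 1), (71 / 75, 3 / 75, 1 / 75)),
        ],
    )
    def test_count_ratio_formula(self, counts, expected):
        node = dt.TreeNode(counts=np.asarray(counts))
        np.testing.assert_allclose(node.probabilities, expected, rtol=0, atol=0)

    def test_exact_rational_identity(self):
        """Probabilities are exactly counts/total, not merely close."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 100, size=3)
            if counts.sum() == 0:
                continue
            node = dt.TreeNode(counts=counts)
            for p, c in zip(node.probabilities, counts):
                assert p == c / counts.sum()

    def test_empty_leaf_rejected(self):
        with pytest.raises(ValueError):
            dt.TreeNode(counts=np.zeros(3, dtype=int)).probabilities


def hand_tree():
    """Depth-3 tree with known counts at every node."""
    l0 = dt.TreeNode(counts=np.array([5, 0, 0]))
    l1 = dt.TreeNode(counts=np.array([0, 3, 0]))
    mid = dt.TreeNode(counts=np.array([5, 3, 0]), feature=2, absent=l0, present=l1)
    l2 = dt.TreeNode(counts=np.array([1, 0, 6]))
    upper = dt.TreeNode(counts=np.array([6, 3, 6]), feature=1, absent=mid, present=l2)
    l3 = dt.TreeNode(counts=np.array([0, 4, 1]))
    root = dt.TreeNode(counts=np.array([6, 7, 7]), feature=0, absent=upper, present=l3)
    return dt.ClassificationTree(root=root, classes=["A", "B", "C"],
                                 feature_names=["f0", "f1", "f2"])


class TestPrune:
    def test_prune_zero_is_identity(self):
        t = hand_tree()
        assert dt.prune(t, 0) is t

    def test_prune_to_root_leaf_is_majority_baseline(self):
        spec = HBondPlantSpec.default(n_frames=100, seed=2)
        fm, _ = gen_hbond_matrix(spec)
        t = dt.fit_tree(fm)
        stump = dt.prune(t, t.depth)
        assert stump.root.is_leaf
        counts = np.asarray([(fm.labels == c).sum() for c in t.classes])
        assert dt.loss(stump, fm) == pytest.approx(1 - counts.max() / counts.sum())

    def test_deepest_level_collapsed_with_merged_counts(self):
        t = hand_tree()
        assert t.depth == 3
        pruned = dt.prune(t, 1)
        assert pruned.depth == 2
        # the depth-3 subtree (mid) becomes a leaf with summed counts
        collapsed = pruned.root.absent.absent
        assert collapsed.is_leaf
        np.testing.assert_array_equal(collapsed.counts, [5, 3, 0])
        # untouched shallow leaf survives
        assert pruned.root.present.is_leaf
        np.testing.assert_array_equal(pruned.root.present.counts, [0, 4, 1])

    def test_out_of_range_rejected(self):
        t = hand_tree()
        with pytest.raises(ValueError):
            dt.prune(t, t.depth + 1)
        with pytest.raises(ValueError):
            dt.prune(t, -1)


class TestLossAndCurve:
    def test_perfect_tree_zero_loss(self):
        fm = fm_from([[1], [0]], ["A", "B"])
        assert dt.loss(dt.fit_tree(fm), fm) == 0.0

    def test_balanced_majority_baseline_is_two_thirds(self):
        fm = fm_from([[0]] * 6, ["A", "A", "B", "B", "C", "C"])
        t = dt.fit_tree(fm)
        assert dt.loss(t, fm) == pytest.approx(2 / 3)

    def test_loss_non_decreasing_under_pruning(self):
        for seed in range(5):
            spec = HBondPlantSpec.default(n_frames=150, seed=seed)
            fm, _ = gen_hbond_matrix(spec)
            t = dt.fit_tree(fm)
            losses = [dt.loss(dt.prune(t, k), fm) for k in range(t.depth + 1)]
            assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_curve_endpoints(self):
        spec = HBondPlantSpec.default(n_frames=150, seed=1)
        fm, _ = gen_hbond_matrix(spec)
        t = dt.fit_tree(fm)
        curve = dt.prune_curve(t, fm)
        assert len(curve) == t.depth + 1
        assert curve["loss"].iloc[0] == dt.loss(t, fm)
        counts = np.asarray([(fm.labels == c).sum() for c in t.classes])
        assert curve["loss"].iloc[-1] == pytest.approx(1 - counts.max() / counts.sum())


class TestPredict:
    def test_two_bond_path_labels_like_flow_chart(self):
        """A frame showing both discriminative bonds follows the two-split
        path to that leaf's class — the flow-chart reading of the tree."""
        matrix = [[1, 1], [1, 1], [1, 0], [0, 0], [0, 1], [0, 0]]
        labels = ["Cis", "Cis", "Carbo", "FdU", "Carbo", "FdU"]
        t = dt.fit_tree(fm_from(matrix, labels,
                                descriptors=["Thr781–ADP", "Ala517–Cyt4"]))
        label, probs = dt.predict(t, np.array([1, 1]))
        assert label == "Cis"
        assert probs.sum() == pytest.approx(1.0)

    def test_probabilities_sum_to_one_everywhere(self):
        spec = HBondPlantSpec.default(n_frames=100, seed=4)
        fm, _ = gen_hbond_matrix(spec)
        t = dt.fit_tree(fm)
        _, probs = dt.predict(t, fm.matrix)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_schema_mismatch_rejected(self):
        fm = fm_from([[1], [0]], ["A", "B"])
        t = dt.fit_tree(fm)
        with pytest.raises(dt.SchemaError):
            dt.predict(t, np.array([1, 0, 1]))


class TestExport:
    def test_json_round_trip_byte_identical(self):
        spec = HBondPlantSpec.default(n_frames=80, seed=6)
        fm, _ = gen_hbond_matrix(spec)
        t = dt.fit_tree(fm)
        doc = dt.export_tree(t)
        again = dt.export_tree(dt.import_tree(doc))
        assert doc == again
        json.loads(doc)  # valid JSON

    def test_round_trip_preserves_predictions(self):
        spec = HBondPlantSpec.default(n_frames=80, seed=7)
        fm, _ = gen_hbond_matrix(spec)
        t = dt.fit_tree(fm)
        t2 = dt.import_tree(dt.export_tree(t))
        l1, _ = dt.predict(t, fm.matrix)
        l2, _ = dt.predict(t2, fm.matrix)
        np.testing.assert_array_equal(l1, l2)
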