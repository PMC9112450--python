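"""Rule extraction, exact minimization and tree reconstruction.

The semantic oracle throughout is exhaustive cell enumeration: two trees (or
a tree and a DNF) are equivalent iff they label every cell of the joint
threshold grid identically. Minimality on Boolean instances is checked
against an independent Quine-McCluskey/Petrick implementation (sympy's
SOPform) and against brute-force subset search over prime implicants.
"""

import itertools

import numpy as np
import pytest

from akiforest.boolmin import (
    Atom,
    DNF,
    GridTooLargeError,
    Term,
    build_cell_grid,
    dnf_to_tree,
    format_dnf,
    minimize_dnf,
    parse_dnf,
    prune_forest,
    prune_tree,
    tree_to_dnf,
)
from akiforest.boolmin import _prime_implicants, _cover_masks
from akiforest.forest import DecisionTreeModel, HyperParams, Leaf, Split, fit_forest

from conftest import random_tree_dataset

INF = float("inf")


def depth1_tree():
    return DecisionTreeModel(
        root=Split("size", 4.0, left=Leaf(1), right=Leaf(0)),
        feature_names=("size",),
    )


def three_branch_tree():
    # (x1<=5, x2<=3 -> A), (x1<=5, x2>3 -> A), (x1>5 -> B)
    return DecisionTreeModel(
        root=Split("x1", 5.0,
                   left=Split("x2", 3.0, left=Leaf(1), right=Leaf(1)),
                   right=Leaf(0)),
        feature_names=("x1", "x2"),
    )


def grid_equivalent(tree_a, tree_b):
    """Exhaustive oracle: equality on every cell of the joint threshold grid."""
    thr = {}
    for t in (tree_a, tree_b):
        for f, ts in t.thresholds().items():
            thr.setdefault(f, set()).update(ts)
    features = sorted(thr) or ["dummy"]
    axes = []
    for f in features:
        ts = sorted(thr.get(f, []))
        axes.append(ts + [(ts[-1] + 1.0) if ts else 0.0])
    points = np.array(list(itertools.product(*axes)))
    a = DecisionTreeModel(tree_a.root, tuple(features)).predict(points)
    b = DecisionTreeModel(tree_b.root, tuple(features)).predict(points)
    return (a == b).all()


class TestTreeToDnf:
    def test_depth1_single_term(self):
        dnf = tree_to_dnf(depth1_tree(), 1)
        assert dnf.terms == (Term((("size", -INF, 4.0),)),)

    def test_three_branch_transcription(self):
        dnf = tree_to_dnf(three_branch_tree(), 1)
        assert len(dnf.terms) == 2
        for term in dnf.terms:
            d = {f: (lo, hi) for f, lo, hi in term.intervals}
            assert d["x1"] == (-INF, 5.0)

    def test_nested_same_feature_path_canonicalizes(self):
        tree = DecisionTreeModel(
            root=Split("x1", 5.0,
                       left=Split("x1", 3.0, left=Leaf(1), right=Leaf(0)),
                       right=Leaf(0)),
            feature_names=("x1",),
        )
        dnf = tree_to_dnf(tree, 1)
        assert dnf.terms == (Term((("x1", -INF, 3.0),)),)

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="not produced"):
            tree_to_dnf(depth1_tree(), 7)


class TestCellGrid:
    def test_depth1_two_cells(self):
        grid = build_cell_grid(depth1_tree())
        assert grid.n_cells == 2
        assert grid.labels.tolist() == [1, 0]

    def test_product_rule(self):
        tree = DecisionTreeModel(
            root=Split("f1", 2.0,
                       left=Split("f2", 1.0, left=Leaf(0), right=Leaf(1)),
                       right=Split("f1", 5.0, left=Leaf(1), right=Leaf(0))),
            feature_names=("f1", "f2"),
        )
        grid = build_cell_grid(tree)
        assert grid.n_cells == 6  # 3 intervals on f1 x 2 on f2

    @pytest.mark.parametrize("seed", range(8))
    def test_cell_labels_match_tree_at_representatives(self, seed):
        data = random_tree_dataset(seed, n=100, n_features=3)
        tree = fit_forest(data, HyperParams(depth=4, MSPL=1, LC=10, n=1), seed=seed).trees[0]
        grid = build_cell_grid(tree)
        reps = grid.representatives()
        preds = DecisionTreeModel(tree.root, grid.features).predict(reps)
        assert (preds == grid.labels.ravel()).all()

    def test_cap_raises_grid_error(self):
        data = random_tree_dataset(0, n=400, n_features=6)
        tree = fit_forest(data, HyperParams(depth=5, MSPL=1, LC=32, n=1), seed=0).trees[0]
        with pytest.raises(GridTooLargeError, match="greedy"):
            build_cell_grid(tree, cap=10)


class TestMinimizeDnf:
    def test_sibling_terms_merge(self):
        tree = three_branch_tree()
        grid = build_cell_grid(tree)
        minimized = minimize_dnf(tree_to_dnf(tree, 1), grid)
        assert minimized.terms == (Term((("x1", -INF, 5.0),)),)

    def test_already_prime_is_idempotent(self):
        tree = depth1_tree()
        grid = build_cell_grid(tree)
        once = minimize_dnf(tree_to_dnf(tree, 1), grid)
        assert minimize_dnf(once, grid) == once

    def test_inconsistent_terms_raise(self):
        grid = build_cell_grid(three_branch_tree())
        wrong = DNF(label=1, terms=(Term((("x1", 5.0, INF),)),))
        with pytest.raises(ValueError, match="inconsistent"):
            minimize_dnf(wrong, grid)

    @pytest.mark.parametrize("seed", range(25))
    def test_equivalence_and_nonincrease_on_random_trees(self, seed):
        data = random_tree_dataset(seed, n=150, n_features=4)
        tree = fit_forest(data, HyperParams(depth=5, MSPL=1, LC=16, n=1), seed=seed).trees[0]
        grid = build_cell_grid(tree)
        for label in {leaf.label for leaf in tree.leaves()}:
            raw = tree_to_dnf(tree, label)
            minimized = minimize_dnf(raw, grid)
            assert minimized.n_terms <= raw.n_terms
            # exhaustive region check against the tree
            covered = np.zeros(grid.shape, dtype=bool)
            for term in minimized.terms:
                box = [slice(None)] * len(grid.features)
                for f, lo, hi in term.intervals:
                    j = grid.features.index(f)
                    ts = list(grid.thresholds[j])
                    a = 0 if lo == -INF else ts.index(lo) + 1
                    b = len(ts) if hi == INF else ts.index(hi)
                    box[j] = slice(a, b + 1)
                covered[tuple(box)] = True
            assert (covered == (grid.labels == label)).all()

    @pytest.mark.parametrize("seed", range(25))
    def test_every_output_term_is_prime(self, seed):
        """Relaxing any bound of a minimized term by one grid step must
        cover a cell of the opposite class."""
        data = random_tree_dataset(seed + 100, n=150, n_features=3)
        tree = fit_forest(data, HyperParams(depth=5, MSPL=1, LC=16, n=1), seed=seed).trees[0]
        grid = build_cell_grid(tree)
        onset = grid.labels == 1
        if not onset.any() or onset.all():
            pytest.skip("degenerate single-class tree")
        from akiforest.boolmin import _term_to_box
        minimized = minimize_dnf(tree_to_dnf(tree, 1), grid)
        for term in minimized.terms:
            box = _term_to_box(term, grid)
            for d, (a, b) in enumerate(box):
                for edge in (a - 1, b + 1):
                    if not 0 <= edge < grid.shape[d]:
                        continue
                    slab = tuple(
                        slice(edge, edge + 1) if j == d else slice(lo, hi + 1)
                        for j, (lo, hi) in enumerate(box)
                    )
                    assert not onset[slab].all(), "term bound can be relaxed"


def truth_table_min_terms_sympy(tt: int):
    """Independent minimal SOP term count via sympy's Quine-McCluskey."""
    from sympy import symbols
    from sympy.logic import SOPform
    from sympy.logic.boolalg import Or, BooleanTrue, BooleanFalse

    minterms = [[i >> b & 1 for b in range(4)] for i in range(16) if tt >> i & 1]
    if not minterms:
        return 0
    expr = SOPform(symbols("x0 x1 x2 x3"), minterms)
    if isinstance(expr, BooleanTrue):
        return 1
    if isinstance(expr, BooleanFalse):
        return 0
    return len(expr.args) if isinstance(expr, Or) else 1


def boolean_grid(tt: int):
    """Encode a 4-variable truth table as a 2^4 cell grid (one threshold per
    feature: value<=0.5 is 'false')."""
    from akiforest.boolmin import CellGrid

    labels = np.zeros((2, 2, 2, 2), dtype=int)
    for i in range(16):
        idx = tuple(i >> b & 1 for b in range(4))
        labels[idx] = tt >> i & 1
    return CellGrid(
        features=("x0", "x1", "x2", "x3"),
        thresholds=((0.5,),) * 4,
        labels=labels,
    )


def full_cover_dnf(grid):
    """One term per on-cell: the unminimized canonical DNF."""
    terms = []
    for idx in np.argwhere(grid.labels == 1):
        atoms = []
        for j, i in enumerate(idx):
            f = grid.features[j]
            atoms.append(Atom(f, 0.5, "<=" if i == 0 else ">"))
        terms.append(Term.from_atoms(atoms))
    return DNF(label=1, terms=tuple(terms))


class TestBooleanMinimality:
    @pytest.mark.parametrize("seed", [0])
    def test_term_count_matches_sympy_and_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        tables = rng.integers(1, 2 ** 16, size=60)
        for tt in tables:
            tt = int(tt)
            grid = boolean_grid(tt)
            ours = minimize_dnf(full_cover_dnf(grid), grid)
            assert ours.n_terms == truth_table_min_terms_sympy(tt)
            # brute force over subsets of our primes for small instances
            onset = grid.labels == 1
            primes = _prime_implicants(onset)
            if len(primes) <= 12:
                masks = _cover_masks(primes, onset)
                universe = (1 << int(onset.sum())) - 1
                brute = next(
                    k for k in range(1, len(primes) + 1)
                    if any(
                        _union(c) == universe
                        for c in itertools.combinations(masks, k)
                    )
                )
                assert ours.n_terms == brute

    def test_constant_functions(self):
        grid = boolean_grid(0xFFFF)
        assert minimize_dnf(full_cover_dnf(grid), grid).terms == (Term(),)
        grid0 = boolean_grid(0)
        assert minimize_dnf(DNF(label=1, terms=()), grid0).terms == ()


def _union(masks):
    out = 0
    for m in masks:
        out |= m
    return out


class TestDnfToTree:
    def test_two_class_split_gives_depth1_tree(self):
        grid = build_cell_grid(depth1_tree())
        dnfs = [
            DNF(label=1, terms=(Term((("size", -INF, 4.0),)),)),
            DNF(label=0, terms=(Term((("size", 4.0, INF),)),)),
        ]
        tree = dnf_to_tree(dnfs, grid)
        assert tree.n_leaves == 2 and tree.depth == 1

    def test_three_branch_example_shrinks_to_two_leaves(self):
        tree = three_branch_tree()
        grid = build_cell_grid(tree)
        dnfs = [minimize_dnf(tree_to_dnf(tree, l), grid) for l in (0, 1)]
        rebuilt = dnf_to_tree(dnfs, grid)
        assert tree.n_leaves == 3 and rebuilt.n_leaves == 2

    def test_non_partition_raises(self):
        grid = build_cell_grid(depth1_tree())
        overlapping = [
            DNF(label=1, terms=(Term(),)),
            DNF(label=0, terms=(Term((("size", 4.0, INF),)),)),
        ]
        with pytest.raises(ValueError, match="partition"):
            dnf_to_tree(overlapping, grid)

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_is_pointwise_identical(self, seed):
        data = random_tree_dataset(seed + 50, n=120, n_features=3)
        tree = fit_forest(data, HyperParams(depth=4, MSPL=1, LC=12, n=1), seed=seed).trees[0]
        grid = build_cell_grid(tree)
        labels = sorted({leaf.label for leaf in tree.leaves()})
        if len(labels) < 2:
            pytest.skip("single-class tree")
        dnfs = [minimize_dnf(tree_to_dnf(tree, l), grid) for l in labels]
        rebuilt = dnf_to_tree(dnfs, grid)
        reps = grid.representatives()
        np.testing.assert_array_equal(
            rebuilt.predict(reps),
            DecisionTreeModel(tree.root, grid.features).predict(reps),
        )


class TestPruneTree:
    def test_redundant_siblings_collapse(self):
        tree = DecisionTreeModel(
            root=Split("a", 2.0, left=Leaf(1), right=Leaf(1)),
            feature_names=("a",),
        )
        assert prune_tree(tree).n_leaves == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_equivalence_leafcount_idempotence(self, seed):
        data = random_tree_dataset(seed + 200, n=150, n_features=4)
        tree = fit_forest(data, HyperParams(depth=5, MSPL=1, LC=16, n=1), seed=seed).trees[0]
        pruned = prune_tree(tree)
        assert grid_equivalent(tree, pruned)
        assert pruned.n_leaves <= tree.n_leaves
        again = prune_tree(pruned)
        assert again.n_leaves == pruned.n_leaves
        assert again.root == pruned.root

    def test_class_dnfs_of_pruned_tree_still_partition(self):
        data = random_tree_dataset(999, n=150, n_features=3)
        tree = fit_forest(data, HyperParams(depth=5, MSPL=1, LC=16, n=1), seed=1).trees[0]
        pruned = prune_tree(tree)
        grid = build_cell_grid(pruned)
        cover = np.zeros(grid.shape, dtype=int)
        for label in {leaf.label for leaf in pruned.leaves()}:
            mask = np.zeros(grid.shape, dtype=bool)
            from akiforest.boolmin import _paint, _term_to_box
            for term in tree_to_dnf(pruned, label).terms:
                _paint(mask, _term_to_box(term, grid))
            cover += mask
        assert (cover == 1).all()


class TestPruneForest:
    def test_forest_equals_original_on_probes(self, small_forest):
        pruned = prune_forest(small_forest)
        assert pruned.pruned
        probe = np.random.default_rng(3).uniform(-10, 250, size=(2000, 8))
        np.testing.assert_array_equal(
            pruned.vote_fraction(probe), small_forest.vote_fraction(probe)
        )

    def test_minimal_forest_unchanged(self):
        tree = depth1_tree()
        from akiforest.forest import ForestModel
        forest = ForestModel(
            trees=(tree,),
            hyper=HyperParams(depth=1, MSPL=1, LC=2, n=1),
            seed=0,
            feature_names=("size",),
        )
        pruned = prune_forest(forest)
        assert pruned.trees[0].root == tree.root

    def test_pruned_leaf_counts_vary_across_trees(self, cohort723):
        model = fit_forest(cohort723, HyperParams(depth=5, MSPL=5, LC=16, n=15), seed=2)
        pruned = prune_forest(model)
        counts = {t.n_leaves for t in pruned.trees}
        assert len(counts) > 1


class TestTextForm:
    def test_round_trip_exact(self):
        text = "AKI := (creatinine>1.4) | (renal>7.0 & size<=4.0)"
        dnf = parse_dnf(text)
        assert format_dnf(dnf) == text
        assert parse_dnf(format_dnf(dnf)) == dnf

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError, match="separator"):
            parse_dnf("size<=4.0")
        with pytest.raises(ValueError, match="atom"):
            parse_dnf("AKI := (size==4.0)")

    def test_infeasible_term_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            parse_dnf("AKI := (size<=3.0 & size>5.0)")
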