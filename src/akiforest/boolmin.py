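"""Rule minimization for decision trees (the "SAT pruning" pass).

Every root-to-leaf branch of an axis-aligned tree is a conjunction of
threshold predicates ``x_i`` (``feature <= t`` / ``feature > t``); branches
sharing a class label, OR-ed together, give that class a formula in
disjunctive normal form (DNF). The distinct thresholds of a tree partition
feature space into a finite *cell grid*, which gives the formula decidable
semantics: two formulas are equivalent iff they label every cell alike.

Minimization is exact two-level logic minimization over that grid — a
multi-valued Quine-McCluskey: prime implicants are the maximal axis-aligned
boxes of on-set cells, and a minimum-cardinality cover is selected by
branch-and-bound (greedy set cover beyond a size cap). The minimized
per-class DNFs are then rebuilt into a semantically identical, never larger,
decision tree.

Intervals are half-open on the left: a term constrains each feature to
``lo < x <= hi``, matching the ``<=``-goes-left split convention.
"""

from __future__ import annotations

import itertools
import re
import warnings
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .forest import DecisionTreeModel, ForestModel, Leaf, Node, Split

DEFAULT_CELL_CAP = 10 ** 6
EXACT_COVER_CAP = 64  # max prime count for branch-and-bound cover search

_INF = float("inf")


# ---------------------------------------------------------------------------
# Atoms, terms, DNF
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Atom:
    """One threshold predicate: ``feature <= threshold`` or ``feature > threshold``."""

    feature: str
    threshold: float
    op: str  # "<=" or ">"

    def __post_init__(self) -> None:
        if self.op not in ("<=", ">"):
            raise ValueError(f"atom operator must be '<=' or '>', got {self.op!r}")
        if not np.isfinite(self.threshold):
            raise ValueError(f"atom threshold must be finite, got {self.threshold}")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value > self.threshold

    def __str__(self) -> str:
        return f"{self.feature}{self.op}{self.threshold!r}"


@dataclass(frozen=True)
class Term:
    """Conjunction of atoms in canonical interval form.

    ``intervals`` holds one ``(feature, lo, hi)`` triple per constrained
    feature, sorted by feature name, meaning ``lo < x <= hi``. An empty
    tuple is the always-true term.
    """

    intervals: tuple[tuple[str, float, float], ...] = ()

    @staticmethod
    def from_atoms(atoms: Iterable[Atom]) -> "Term | None":
        """Canonicalize a conjunction; ``None`` if some interval is empty."""
        lo: dict[str, float] = {}
        hi: dict[str, float] = {}
        for a in atoms:
            if a.op == ">":
                lo[a.feature] = max(lo.get(a.feature, -_INF), a.threshold)
            else:
                hi[a.feature] = min(hi.get(a.feature, _INF), a.threshold)
        feats = sorted(set(lo) | set(hi))
        ivs = []
        for f in feats:
            l, h = lo.get(f, -_INF), hi.get(f, _INF)
            if l >= h:
                return None  # infeasible, e.g. x<=3 AND x>5
            ivs.append((f, l, h))
        return Term(tuple(ivs))

    def atoms(self) -> tuple[Atom, ...]:
        out = []
        for f, lo, hi in self.intervals:
            if lo > -_INF:
                out.append(Atom(f, lo, ">"))
            if hi < _INF:
                out.append(Atom(f, hi, "<="))
        return tuple(out)

    @property
    def n_atoms(self) -> int:
        return sum((lo > -_INF) + (hi < _INF) for _, lo, hi in self.intervals)

    def satisfied_by(self, record: Mapping[str, float]) -> bool:
        return all(lo < record[f] <= hi for f, lo, hi in self.intervals)

    def __str__(self) -> str:
        if not self.intervals:
            return "(true)"
        return "(" + " & ".join(str(a) for a in self.atoms()) + ")"


@dataclass(frozen=True)
class DNF:
    """Disjunction of terms for one class label."""

    label: int
    terms: tuple[Term, ...]

    def satisfied_by(self, record: Mapping[str, float]) -> bool:
        return any(t.satisfied_by(record) for t in self.terms)

    @property
    def n_terms(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# Text form:  "AKI := (size<=4.0 & renal>7.0) | (creatinine>1.4)"
# ---------------------------------------------------------------------------

DEFAULT_LABEL_NAMES = {1: "AKI", 0: "non-AKI"}

_ATOM_RE = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*)\s*(<=|>)\s*([-+0-9.eE]+)\s*")


def format_dnf(dnf: DNF, label_names: Mapping[int, str] = DEFAULT_LABEL_NAMES) -> str:
    name = label_names.get(dnf.label, str(dnf.label))
    if not dnf.terms:
        return f"{name} := (false)"
    return f"{name} := " + " | ".join(str(t) for t in sorted(dnf.terms, key=_term_key))


def parse_dnf(text: str, label_names: Mapping[int, str] = DEFAULT_LABEL_NAMES) -> DNF:
    if ":=" not in text:
        raise ValueError(f"DNF text lacks ':=' separator: {text!r}")
    name, body = (part.strip() for part in text.split(":=", 1))
    by_name = {v: k for k, v in label_names.items()}
    if name not in by_name:
        raise ValueError(f"unknown class name {name!r}; expected one of {sorted(by_name)}")
    label = by_name[name]
    terms: list[Term] = []
    if body != "(false)":
        for chunk in body.split("|"):
            chunk = chunk.strip()
            if not (chunk.startswith("(") and chunk.endswith(")")):
                raise ValueError(f"term must be parenthesized: {chunk!r}")
            inner = chunk[1:-1].strip()
            if inner == "true":
                terms.append(Term())
                continue
            atoms = []
            for piece in inner.split("&"):
                m = _ATOM_RE.fullmatch(piece)
                if not m:
                    raise ValueError(f"cannot parse atom {piece!r}")
                atoms.append(Atom(m.group(1), float(m.group(3)), m.group(2)))
            term = Term.from_atoms(atoms)
            if term is None:
                raise ValueError(f"infeasible term {chunk!r}")
            terms.append(term)
    return DNF(label=label, terms=tuple(terms))


def _term_key(term: Term):
    return tuple(
        (f, 0 if lo > -_INF else 1, lo, hi) for f, lo, hi in term.intervals
    )


# ---------------------------------------------------------------------------
# Cell grid
# ---------------------------------------------------------------------------

class GridTooLargeError(ValueError):
    """Raised when the threshold grid exceeds the configured cell cap."""


@dataclass(frozen=True)
class CellGrid:
    """Finite partition of feature space by a tree's distinct thresholds.

    Per feature with thresholds ``t_0 < ... < t_{m-1}``, interval index ``i``
    denotes ``(t_{i-1}, t_i]`` (with sentinels at +-inf), so each feature
    contributes ``m + 1`` intervals. ``labels[idx]`` maps each cell to its
    class.
    """

    features: tuple[str, ...]
    thresholds: tuple[tuple[float, ...], ...]
    labels: np.ndarray  # int array, shape = tuple(m_f + 1)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(t) + 1 for t in self.thresholds)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape, dtype=np.int64)) if self.features else 1

    def representative(self, feature_pos: int, interval_idx: int) -> float:
        """A point inside interval ``interval_idx`` of the given feature."""
        ts = self.thresholds[feature_pos]
        if not ts:
            return 0.0
        if interval_idx < len(ts):
            return ts[interval_idx]  # right-closed: t_i itself lies in (t_{i-1}, t_i]
        return ts[-1] + 1.0

    def representatives(self) -> np.ndarray:
        """One representative point per cell; shape (n_cells, n_features)."""
        axes = [
            [self.representative(j, i) for i in range(m)]
            for j, m in enumerate(self.shape)
        ]
        if not axes:
            return np.zeros((1, 0))
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def cell_of(self, record: Mapping[str, float]) -> tuple[int, ...]:
        idx = []
        for j, f in enumerate(self.features):
            ts = self.thresholds[j]
            idx.append(bisect_left(ts, record[f]))
        return tuple(idx)


def build_cell_grid(
    tree: DecisionTreeModel, cap: int = DEFAULT_CELL_CAP
) -> CellGrid:
    """Enumerate the tree's threshold grid and label every cell by prediction."""
    thr = tree.thresholds()
    features = tuple(sorted(thr))
    thresholds = tuple(tuple(thr[f]) for f in features)
    shape = tuple(len(t) + 1 for t in thresholds)
    n_cells = int(np.prod(shape, dtype=np.int64)) if features else 1
    if n_cells > cap:
        raise GridTooLargeError(
            f"cell grid has {n_cells} cells (cap {cap}); use the greedy "
            "structural simplification fallback for this tree"
        )
    grid = CellGrid(features=features, thresholds=thresholds,
                    labels=np.zeros(shape or (), dtype=int))
    reps = grid.representatives()
    tree_on_grid = DecisionTreeModel(root=tree.root, feature_names=features)
    labels = tree_on_grid.predict(reps).reshape(shape or ())
    return CellGrid(features=features, thresholds=thresholds, labels=labels)


# ---------------------------------------------------------------------------
# Tree -> DNF
# ---------------------------------------------------------------------------

def tree_to_dnf(tree: DecisionTreeModel, label: int) -> DNF:
    """Collect each branch ending in ``label`` as a canonical term."""
    leaf_labels = {leaf.label for leaf in tree.leaves()}
    if label not in leaf_labels:
        raise ValueError(
            f"label {label!r} not produced by this tree (labels: {sorted(leaf_labels)})"
        )
    terms: list[Term] = []

    def walk(node: Node, atoms: list[Atom]) -> None:
        if node.is_leaf:
            if node.label == label:
                term = Term.from_atoms(atoms)
                if term is not None:  # infeasible branches are dropped
                    terms.append(term)
            return
        walk(node.left, atoms + [Atom(node.feature, node.threshold, "<=")])
        walk(node.right, atoms + [Atom(node.feature, node.threshold, ">")])

    walk(tree.root, [])
    return DNF(label=label, terms=tuple(sorted(terms, key=_term_key)))


# ---------------------------------------------------------------------------
# Terms <-> index boxes on a grid
# ---------------------------------------------------------------------------

def _term_to_box(term: Term, grid: CellGrid) -> tuple[tuple[int, int], ...]:
    """Inclusive per-feature interval-index ranges covered by a term."""
    bounds = {f: (lo, hi) for f, lo, hi in term.intervals}
    box = []
    for j, f in enumerate(grid.features):
        m = len(grid.thresholds[j])
        lo, hi = bounds.pop(f, (-_INF, _INF))
        ts = grid.thresholds[j]
        a = 0 if lo == -_INF else ts.index(lo) + 1 if lo in ts else None
        b = m if hi == _INF else ts.index(hi) if hi in ts else None
        if a is None or b is None:
            raise ValueError(
                f"term bound on {f!r} not aligned with the grid thresholds"
            )
        box.append((a, b))
    if bounds:
        raise ValueError(f"term constrains features absent from grid: {sorted(bounds)}")
    return tuple(box)


def _box_to_term(box: Sequence[tuple[int, int]], grid: CellGrid) -> Term:
    ivs = []
    for j, (a, b) in enumerate(box):
        ts = grid.thresholds[j]
        m = len(ts)
        lo = -_INF if a == 0 else ts[a - 1]
        hi = _INF if b == m else ts[b]
        if lo > -_INF or hi < _INF:
            ivs.append((grid.features[j], lo, hi))
    return Term(tuple(ivs))


def _paint(mask: np.ndarray, box: Sequence[tuple[int, int]]) -> None:
    mask[tuple(slice(a, b + 1) for a, b in box)] = True


# ---------------------------------------------------------------------------
# Prime implicants and minimum cover
# ---------------------------------------------------------------------------

def _prime_implicants(onset: np.ndarray) -> list[tuple[tuple[int, int], ...]]:
    """All maximal axis-aligned boxes of True cells.

    Breadth-first expansion from single cells: a box grows one grid step at a
    time while the added slab stays inside the on-set; boxes with no legal
    growth are prime. Every prime is reachable because any sub-box of an
    all-on box is all-on.
    """
    ndim = onset.ndim
    shape = onset.shape
    if ndim == 0:
        return [()] if bool(onset) else []

    def slab_ok(box, dim, idx) -> bool:
        sl = [slice(a, b + 1) for a, b in box]
        sl[dim] = slice(idx, idx + 1)
        return bool(onset[tuple(sl)].all())

    seeds = [tuple((int(i), int(i)) for i in idx) for idx in np.argwhere(onset)]
    visited: set[tuple[tuple[int, int], ...]] = set(seeds)
    queue = list(seeds)
    primes: list[tuple[tuple[int, int], ...]] = []
    while queue:
        box = queue.pop()
        grown = False
        for d in range(ndim):
            a, b = box[d]
            for na, nb, edge in ((a - 1, b, a - 1), (a, b + 1, b + 1)):
                if na < 0 or nb >= shape[d]:
                    continue
                if slab_ok(box, d, edge):
                    grown = True
                    child = box[:d] + ((na, nb),) + box[d + 1:]
                    if child not in visited:
                        visited.add(child)
                        queue.append(child)
        if not grown:
            primes.append(box)
    return sorted(set(primes))


def _box_cost(box: Sequence[tuple[int, int]], shape: Sequence[int]) -> int:
    """Number of atoms the box needs: finite bounds only."""
    return sum((a > 0) + (b < m - 1) for (a, b), m in zip(box, shape))


def _cover_masks(
    primes: Sequence[tuple[tuple[int, int], ...]], onset: np.ndarray
) -> list[int]:
    """Bitmask (over on-cells) of the cells each prime covers."""
    flat_ids = -np.ones(onset.shape, dtype=np.int64)
    cells = np.argwhere(onset)
    for bit, idx in enumerate(cells):
        flat_ids[tuple(idx)] = bit
    masks = []
    for box in primes:
        sl = tuple(slice(a, b + 1) for a, b in box)
        ids = flat_ids[sl].ravel()
        m = 0
        for i in ids:
            m |= 1 << int(i)
        masks.append(m)
    return masks


def _min_cover_exact(
    masks: Sequence[int],
    costs: Sequence[int],
    lexkeys: Sequence,
    universe: int,
) -> list[int]:
    """Branch-and-bound minimum-cardinality cover.

    Objective: fewest primes, then lowest total atom count, then
    lexicographically smallest set of terms. Explores all covers no larger
    than the incumbent's cardinality, so the secondary keys are exact too.
    """
    order = sorted(range(len(masks)), key=lambda i: (costs[i], lexkeys[i]))
    best: list | None = None
    best_key: tuple | None = None

    def covers_of(cell_bit: int) -> list[int]:
        return [i for i in order if masks[i] >> cell_bit & 1]

    def rec(uncovered: int, chosen: list[int], atom_sum: int) -> None:
        nonlocal best, best_key
        if uncovered == 0:
            key = (len(chosen), atom_sum, tuple(sorted(lexkeys[i] for i in chosen)))
            if best_key is None or key < best_key:
                best, best_key = list(chosen), key
            return
        if best_key is not None and len(chosen) + 1 > best_key[0]:
            return
        # branch on the uncovered cell with fewest covering primes
        cell, cands = None, None
        rem = uncovered
        while rem:
            bit = (rem & -rem).bit_length() - 1
            c = covers_of(bit)
            if cands is None or len(c) < len(cands):
                cell, cands = bit, c
                if len(c) <= 1:
                    break
            rem &= rem - 1
        for i in cands or []:
            chosen.append(i)
            rec(uncovered & ~masks[i], chosen, atom_sum + costs[i])
            chosen.pop()

    rec(universe, [], 0)
    assert best is not None
    return best


def _min_cover_greedy(
    masks: Sequence[int], costs: Sequence[int], lexkeys: Sequence, universe: int
) -> list[int]:
    chosen: list[int] = []
    uncovered = universe
    while uncovered:
        best_i = min(
            range(len(masks)),
            key=lambda i: (-bin(masks[i] & uncovered).count("1"), costs[i], lexkeys[i]),
        )
        if masks[best_i] & uncovered == 0:
            raise ValueError("primes do not cover the on-set")  # cannot happen
        chosen.append(best_i)
        uncovered &= ~masks[best_i]
    return chosen


def minimize_dnf(dnf: DNF, grid: CellGrid) -> DNF:
    """Exact two-level minimization of a class DNF over the cell grid.

    The on-set is the set of cells the grid labels ``dnf.label``; the input
    terms must cover exactly that set. The result is a minimum-cardinality
    disjunction of prime implicants covering the on-set and nothing else.
    """
    onset = grid.labels == dnf.label
    covered = np.zeros(grid.shape or (), dtype=bool)
    for term in dnf.terms:
        _paint(covered, _term_to_box(term, grid))
    if not np.array_equal(covered, onset):
        raise ValueError(
            "DNF terms are inconsistent with the grid labels for class "
            f"{dnf.label!r} (term cover != labeled cells)"
        )
    if not onset.any():
        return DNF(label=dnf.label, terms=())
    if onset.all():
        return DNF(label=dnf.label, terms=(Term(),))

    primes = _prime_implicants(onset)
    masks = _cover_masks(primes, onset)
    costs = [_box_cost(b, grid.shape) for b in primes]
    lexkeys = [_term_key(_box_to_term(b, grid)) for b in primes]
    universe = (1 << int(onset.sum())) - 1
    if len(primes) <= EXACT_COVER_CAP:
        chosen = _min_cover_exact(masks, costs, lexkeys, universe)
    else:
        chosen = _min_cover_greedy(masks, costs, lexkeys, universe)
    terms = sorted((_box_to_term(primes[i], grid) for i in chosen), key=_term_key)
    return DNF(label=dnf.label, terms=tuple(terms))


# ---------------------------------------------------------------------------
# DNF -> tree
# ---------------------------------------------------------------------------

def dnf_to_tree(dnfs: Sequence[DNF], grid: CellGrid) -> DecisionTreeModel:
    """Rebuild a decision tree realizing the per-class DNFs exactly.

    The class DNFs must partition the grid cells. Splits are chosen to
    maximize the number of terms fully separated; ties prefer the fewest
    resulting leaves, then the lexicographically first (feature, threshold).
    """
    labels = sorted({d.label for d in dnfs})
    if len(labels) != len(dnfs):
        raise ValueError("duplicate class labels among DNFs")
    class_map = -np.ones(grid.shape or (), dtype=int)
    count_map = np.zeros(grid.shape or (), dtype=int)
    term_boxes: list[tuple[tuple[tuple[int, int], ...], int]] = []
    for d in dnfs:
        covered = np.zeros(grid.shape or (), dtype=bool)
        for term in d.terms:
            box = _term_to_box(term, grid)
            term_boxes.append((box, d.label))
            _paint(covered, box)
        class_map[covered] = d.label
        count_map += covered
    if (count_map != 1).any():
        raise ValueError(
            "class DNFs must partition the grid: "
            f"{int((count_map == 0).sum())} uncovered and "
            f"{int((count_map > 1).sum())} cells claimed by multiple classes"
        )

    if not grid.features:
        tree = DecisionTreeModel(root=Leaf(label=int(class_map[()])), feature_names=())
        return tree

    # candidate split positions: thresholds actually used by some term bound
    # (sufficient: cells of that coarser grid are class-pure; keeps the pass
    # idempotent because a rebuilt tree only ever carries these thresholds)
    used: dict[int, set[int]] = {}
    for box, _ in term_boxes:
        for j, (a, b) in enumerate(box):
            m = len(grid.thresholds[j])
            if a > 0:
                used.setdefault(j, set()).add(a - 1)
            if b < m:
                used.setdefault(j, set()).add(b)

    memo: dict[tuple[tuple[int, int], ...], tuple[Node, int]] = {}

    def build(region: tuple[tuple[int, int], ...]) -> tuple[Node, int]:
        if region in memo:
            return memo[region]
        sl = tuple(slice(a, b + 1) for a, b in region)
        sub = class_map[sl]
        first = int(sub.flat[0])
        if (sub == first).all():
            result = (Leaf(label=first), 1)
            memo[region] = result
            return result

        def intersects(box) -> bool:
            return all(a <= rb and b >= ra for (a, b), (ra, rb) in zip(box, region))

        active = [(box, lab) for box, lab in term_boxes if intersects(box)]
        candidates = []  # (-separated, feature, threshold_value, j, t)
        for j, ts_idx in used.items():
            ra, rb = region[j]
            for t in sorted(ts_idx):
                if not (ra <= t < rb):
                    continue  # split must cut the region
                sep = sum(
                    1 for box, _ in active if box[j][1] <= t or box[j][0] > t
                )
                candidates.append(
                    (-sep, grid.features[j], grid.thresholds[j][t], j, t)
                )
        candidates.sort(key=lambda c: c[0])
        best_sep = candidates[0][0]
        tied = [c for c in candidates if c[0] == best_sep]
        best: tuple[Node, int] | None = None
        best_key: tuple | None = None
        for _, fname, tval, j, t in tied:
            left_region = region[:j] + ((region[j][0], t),) + region[j + 1:]
            right_region = region[:j] + ((t + 1, region[j][1]),) + region[j + 1:]
            lnode, lleaves = build(left_region)
            rnode, rleaves = build(right_region)
            key = (lleaves + rleaves, fname, tval)
            if best_key is None or key < best_key:
                best_key = key
                best = (Split(feature=fname, threshold=tval, left=lnode, right=rnode),
                        lleaves + rleaves)
        assert best is not None
        memo[region] = best
        return best

    full = tuple((0, m - 1) for m in grid.shape)
    root, n_leaves = build(full)
    tree = DecisionTreeModel(root=root, feature_names=grid.features)

    # internal verification: rebuilt tree equals the DNF label on every cell
    reps = grid.representatives()
    if not np.array_equal(tree.predict(reps).reshape(grid.shape), class_map):
        raise AssertionError("rebuilt tree disagrees with the DNF partition")
    total_terms = sum(d.n_terms for d in dnfs)
    if n_leaves > 2 * total_terms:
        warnings.warn(
            f"rebuilt tree uses {n_leaves} leaves for {total_terms} terms",
            RuntimeWarning,
            stacklevel=2,
        )
    return tree


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_tree(
    tree: DecisionTreeModel, cap: int = DEFAULT_CELL_CAP
) -> DecisionTreeModel:
    """Minimize a tree's per-class rules and rebuild an equivalent tree.

    The result predicts identically on every grid cell (verified internally),
    never has more leaves than the input, and the pass is idempotent. Trees
    whose threshold grid exceeds ``cap`` cells fall back to structural
    simplification (infeasible-branch removal + same-label sibling collapse).
    """
    try:
        grid = build_cell_grid(tree, cap=cap)
    except GridTooLargeError:
        return _structural_simplify(tree)
    leaf_labels = sorted({leaf.label for leaf in tree.leaves()})
    if len(leaf_labels) == 1:
        return DecisionTreeModel(root=Leaf(label=leaf_labels[0]),
                                 feature_names=tree.feature_names)
    dnfs = [minimize_dnf(tree_to_dnf(tree, lab), grid) for lab in leaf_labels]
    rebuilt = dnf_to_tree(dnfs, grid)
    rebuilt = DecisionTreeModel(root=rebuilt.root, feature_names=tree.feature_names)
    if rebuilt.n_leaves > tree.n_leaves:  # guard: never grow the tree
        return tree
    return rebuilt


def prune_forest(model: ForestModel, cap: int = DEFAULT_CELL_CAP) -> ForestModel:
    """Prune every tree independently; forest votes are provably unchanged."""
    pruned = [prune_tree(t, cap=cap) for t in model.trees]
    return model.with_trees(pruned, pruned=True)


def _structural_simplify(tree: DecisionTreeModel) -> DecisionTreeModel:
    """Cheap fallback: drop branches made infeasible by their own path and
    merge sibling leaves that share a label. Linear in tree size."""

    def simp(node: Node, lo: dict[str, float], hi: dict[str, float]) -> Node:
        if node.is_leaf:
            return node
        f, t = node.feature, node.threshold
        if t >= hi.get(f, _INF):
            return simp(node.left, lo, hi)
        if t <= lo.get(f, -_INF):
            return simp(node.right, lo, hi)
        left = simp(node.left, lo, {**hi, f: min(hi.get(f, _INF), t)})
        right = simp(node.right, {**lo, f: max(lo.get(f, -_INF), t)}, hi)
        if left.is_leaf and right.is_leaf and left.label == right.label:
            return Leaf(label=left.label)
        return Split(feature=f, threshold=t, left=left, right=right)

    return DecisionTreeModel(root=simp(tree.root, {}, {}),
                             feature_names=tree.feature_names)
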