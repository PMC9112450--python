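"""Human-readable explanations for forest predictions.

After pruning, each tree's class rules are minimal DNFs, so the terms a
patient satisfies *are* the model's reasoning. For each tree that agrees
with the forest's vote we report the shortest satisfied term of that tree's
winning-class DNF; the summary ranks distinct terms by brevity (atom count)
and then by how many trees relied on them — the shortest, most widely shared
rule comes first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

from functools import lru_cache

from .boolmin import (
    DEFAULT_LABEL_NAMES,
    DNF,
    GridTooLargeError,
    Term,
    build_cell_grid,
    minimize_dnf,
    tree_to_dnf,
    _term_key,
)
from .forest import DecisionTreeModel, ForestModel
from .records import PatientRecord


@lru_cache(maxsize=4096)
def _minimized_rules(tree: DecisionTreeModel, label: int) -> DNF:
    """The tree's minimal DNF for ``label`` (branch terms carry incidental
    path constraints; the prime-implicant cover is what we quote)."""
    dnf = tree_to_dnf(tree, label)
    try:
        grid = build_cell_grid(tree)
    except GridTooLargeError:
        return dnf
    return minimize_dnf(dnf, grid)


@dataclass(frozen=True)
class Explanation:
    label: int
    confidence: float
    per_tree: tuple[Term, ...]              # one satisfied term per agreeing tree
    summary: tuple[tuple[Term, int], ...]   # (term, n_trees), shortest first

    def to_json(self, label_names: Mapping[int, str] = DEFAULT_LABEL_NAMES) -> str:
        return json.dumps(
            {
                "label": label_names.get(self.label, str(self.label)),
                "confidence": self.confidence,
                "rules": [
                    {"term": str(term), "n_trees": n} for term, n in self.summary
                ],
            },
            indent=1,
        )

    def to_text(self, label_names: Mapping[int, str] = DEFAULT_LABEL_NAMES) -> str:
        name = label_names.get(self.label, str(self.label))
        lines = [
            f"Prediction: {name} (confidence {self.confidence:.2f}, "
            f"{len(self.per_tree)} of the agreeing trees explained)",
            "Why:",
        ]
        for term, n in self.summary:
            lines.append(f"  {term}   [{n} tree{'s' if n != 1 else ''}]")
        return "\n".join(lines)


def explain_prediction(
    model: ForestModel, record: PatientRecord | Mapping[str, float]
) -> Explanation:
    """Explain the forest's vote on one complete record.

    Requires a pruned forest (rules are only minimal after
    :func:`~akiforest.boolmin.prune_forest`). Every reported term evaluates
    true on the record; when several terms of one tree's DNF are satisfied,
    the one with the fewest atoms is reported (ties lexicographic).
    """
    if not model.pruned:
        raise ValueError(
            "explanations require minimized rules; run prune_forest() first"
        )
    values = record.as_dict() if isinstance(record, PatientRecord) else dict(record)
    missing = [f for f in model.feature_names if f not in values]
    if missing:
        raise KeyError(f"record is missing features required by the model: {missing}")

    label, confidence = model.predict_record(values)
    per_tree: list[Term] = []
    for tree in model.trees:
        if tree.predict_record(values) != label:
            continue
        leaf_labels = {leaf.label for leaf in tree.leaves()}
        if label not in leaf_labels:
            continue  # cannot happen for an agreeing tree; guard anyway
        dnf = _minimized_rules(tree, label)
        satisfied = [t for t in dnf.terms if t.satisfied_by(values)]
        assert satisfied, "agreeing tree must satisfy one of its winning terms"
        satisfied.sort(key=lambda t: (t.n_atoms, _term_key(t)))
        per_tree.append(satisfied[0])

    counts: dict[Term, int] = {}
    for term in per_tree:
        counts[term] = counts.get(term, 0) + 1
    summary = tuple(
        sorted(counts.items(), key=lambda kv: (kv[0].n_atoms, -kv[1], _term_key(kv[0])))
    )
    return Explanation(
        label=label, confidence=confidence, per_tree=tuple(per_tree), summary=summary
    )
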