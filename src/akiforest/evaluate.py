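"""Cohort splitting, cross-validation, ROC/AUC, grid search, importances.

The balanced 80/20 split mirrors the study protocol: draw many random
splits and keep the one whose training and validation cohorts differ least
on age, gender, smoking and the AKI outcome (sum of absolute standardized
differences), then assert post hoc that no balance feature differs
significantly (Welch t-test for continuous, chi-square for binary,
p > 0.05).

AUC is the midrank Mann-Whitney statistic — the probability that a random
AKI patient outscores a random non-AKI patient — which equals the area
under the empirical ROC curve.

Feature importance follows the removal protocol: a feature's importance is
proportional to the drop in cross-validated accuracy when the model is
retrained without it (negative drops clipped to zero, column normalized to
sum 1). Three columns are reported: *original* (model sees true ischemia
time), *estimated* (model sees the pre-operative KNN estimate IT*), and
*core* (IT*'s mass pushed back onto its seven predictors in proportion to
each predictor's contribution to the surrogate's fivefold R²).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .forest import ForestModel, HyperParams, fit_forest
from .records import LabeledDataset

Builder = Callable[[LabeledDataset, int], object]

DEFAULT_GRID: dict[str, tuple] = {
    "depth": (2, 3, 4, 5),
    "MSPL": (1, 5, 10, 20),
    "LC": (4, 8, 16, 32),
    "n": (25, 50, 100, 150),
}

DEFAULT_BALANCE_FEATURES = ("age", "gender", "smoking")


# ---------------------------------------------------------------------------
# Balanced 80/20 split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    train_indices: np.ndarray
    valid_indices: np.ndarray
    balance_score: float
    p_values: dict[str, float]
    significant_imbalance: bool  # True = warning: some p <= 0.05
    summary: pd.DataFrame        # mean +- sd per cohort per balance feature


def _is_binary(values: np.ndarray) -> bool:
    return set(np.unique(values)).issubset({0, 1})


def _standardized_difference(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    if pooled == 0:
        return 0.0
    return abs(a.mean() - b.mean()) / pooled


def optimized_split(
    data: LabeledDataset,
    ratio: float = 0.8,
    repeats: int = 1000,
    balance_on: Sequence[str] | None = None,
    seed: int = 0,
) -> SplitSpec:
    """Best-of-``repeats`` random split minimizing cohort imbalance."""
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    n = len(data)
    n_train = int(round(ratio * n))
    if balance_on is None:
        balance_on = [c for c in DEFAULT_BALANCE_FEATURES if c in data.frame.columns]
    columns = {c: data.frame[c].to_numpy(dtype=float) for c in balance_on}
    columns["AKI"] = data.y.astype(float)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    for _ in range(repeats):
        perm = rng.permutation(n)
        train, valid = perm[:n_train], perm[n_train:]
        score = sum(
            _standardized_difference(v[train], v[valid]) for v in columns.values()
        )
        if best is None or score < best[0]:
            best = (score, perm)
    score, perm = best
    train, valid = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    p_values: dict[str, float] = {}
    rows = []
    for name, v in columns.items():
        a, b = v[train], v[valid]
        if _is_binary(v):
            table = np.array(
                [[(a == 1).sum(), (a == 0).sum()], [(b == 1).sum(), (b == 0).sum()]]
            )
            if table.min() == 0 and (table.sum(axis=0) == 0).any():
                p = 1.0  # constant feature: no imbalance possible
            else:
                p = float(stats.chi2_contingency(table).pvalue)
        else:
            if a.var() == 0 and b.var() == 0:
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        p_values[name] = p
        rows.append(
            {
                "feature": name,
                "train_mean": a.mean(), "train_sd": a.std(ddof=1),
                "valid_mean": b.mean(), "valid_sd": b.std(ddof=1),
                "p_value": p,
            }
        )
    return SplitSpec(
        train_indices=train,
        valid_indices=valid,
        balance_score=float(score),
        p_values=p_values,
        significant_imbalance=any(p <= 0.05 for p in p_values.values()),
        summary=pd.DataFrame(rows).set_index("feature"),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Empirical ROC points and the midrank Mann-Whitney AUC.

    Returns ``(points, auc)`` where ``points`` has columns (fpr, tpr,
    threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thr]), float(auc)


# ---------------------------------------------------------------------------
# Fivefold cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVResult:
    fold_metrics: pd.DataFrame  # precision, recall, accuracy per fold
    roc_points: np.ndarray
    auc: float
    confusion: np.ndarray          # rows predicted Pos/Neg, cols True/False
    confusion_standard: np.ndarray  # rows actual 0/1, cols predicted 0/1
    scores: np.ndarray = field(repr=False, default=None)
    predictions: np.ndarray = field(repr=False, default=None)
    truths: np.ndarray = field(repr=False, default=None)

    @property
    def precision_mean(self) -> float:
        return float(self.fold_metrics["precision"].mean())

    @property
    def precision_sd(self) -> float:
        return float(self.fold_metrics["precision"].std(ddof=1))

    @property
    def recall_mean(self) -> float:
        return float(self.fold_metrics["recall"].mean())

    @property
    def recall_sd(self) -> float:
        return float(self.fold_metrics["recall"].std(ddof=1))

    @property
    def accuracy_mean(self) -> float:
        return float(self.fold_metrics["accuracy"].mean())


def kfold_cv(
    data: LabeledDataset,
    builder: Builder,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold evaluation of a training procedure.

    ``builder(train_data, seed)`` must return a model exposing
    ``predict_batch(X) -> (labels, positive_scores)``. Pooled out-of-fold
    scores feed the ROC; the confusion matrices are pooled and normalized.
    """
    y = data.y
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(
            f"k={k} folds exceed the minority class count {counts.min()}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(data)
    scores = np.empty(n, dtype=float)
    preds = np.empty(n, dtype=int)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
        model = builder(data.subset(train_idx), seed + fold)
        X_test = data.subset(test_idx).X
        labels, s = model.predict_batch(X_test)
        preds[test_idx] = labels
        scores[test_idx] = s
        tp = int(((labels == 1) & (y[test_idx] == 1)).sum())
        fp = int(((labels == 1) & (y[test_idx] == 0)).sum())
        fn = int(((labels == 0) & (y[test_idx] == 1)).sum())
        rows.append(
            {
                "fold": fold,
                "precision": tp / (tp + fp) if tp + fp else 0.0,
                "recall": tp / (tp + fn) if tp + fn else 0.0,
                "accuracy": float((labels == y[test_idx]).mean()),
            }
        )
    roc_points, auc = roc_and_auc(scores, y)

    tp = int(((preds == 1) & (y == 1)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    # predicted-by-correctness layout: rows Positive/Negative (predicted),
    # columns True/False (was the prediction right)
    confusion = np.array([[tp, fp], [tn, fn]], dtype=float) / n
    confusion_standard = np.array([[tn, fp], [fn, tp]], dtype=float) / n

    # algebra check: pooled precision/recall recompute from the matrix
    if tp + fp:
        assert abs(confusion[0, 0] / (confusion[0, 0] + confusion[0, 1]) - tp / (tp + fp)) < 1e-12
    if tp + fn:
        assert abs(confusion[0, 0] / (confusion[0, 0] + confusion[1, 1]) - tp / (tp + fn)) < 1e-12

    return CVResult(
        fold_metrics=pd.DataFrame(rows).set_index("fold"),
        roc_points=roc_points,
        auc=auc,
        confusion=confusion,
        confusion_standard=confusion_standard,
        scores=scores,
        predictions=preds,
        truths=y.copy(),
    )


# ---------------------------------------------------------------------------
# Grid search over forest hyper-parameters
# ---------------------------------------------------------------------------

def grid_search(
    data: LabeledDataset,
    grid: Mapping[str, Iterable] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[HyperParams, pd.DataFrame]:
    """Exhaustive search; best = highest mean CV accuracy, ties toward the
    simpler model (smaller n, depth, LC; larger MSPL)."""
    grid = dict(grid or DEFAULT_GRID)
    names = ("depth", "MSPL", "LC", "n")
    rows = []
    best: tuple | None = None
    for combo in itertools.product(*(grid[name] for name in names)):
        params = dict(zip(names, combo))
        if params["LC"] > 2 ** params["depth"]:
            continue  # unreachable leaf count
        hyper = HyperParams(**params)
        result = kfold_cv(
            data, builder=lambda d, s: fit_forest(d, hyper, s), k=k, seed=seed
        )
        acc = result.accuracy_mean
        rows.append({**params, "accuracy": acc,
                     "precision": result.precision_mean,
                     "recall": result.recall_mean})
        key = (-acc, params["n"], params["depth"], params["LC"], -params["MSPL"])
        if best is None or key < best[0]:
            best = (key, hyper)
    if best is None:
        raise ValueError("hyper-parameter grid is empty")
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Removal-based feature importance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceTable:
    table: pd.DataFrame  # index: features + IT*; columns original/estimated/core


def feature_importance(
    data: LabeledDataset,
    hyper: HyperParams | None = None,
    k: int = 5,
    seed: int = 0,
    surrogate_target: str = "IT",
    surrogate_k: int = 5,
) -> ImportanceTable:
    """Drop-one-feature importances in three columns (see module docstring)."""
    from .features import oof_surrogate, surrogate_quality

    features = list(data.feature_names)
    if len(features) < 2:
        raise ValueError("importance needs at least two features")
    hyper = hyper or HyperParams(depth=3, MSPL=1, LC=8, n=25)

    def cv_accuracy(d: LabeledDataset) -> float:
        return kfold_cv(
            d, builder=lambda dd, s: fit_forest(dd, hyper, s), k=k, seed=seed
        ).accuracy_mean

    def removal_column(d: LabeledDataset) -> dict[str, float]:
        base = cv_accuracy(d)
        drops = {}
        for f in d.feature_names:
            rest = [g for g in d.feature_names if g != f]
            drops[f] = max(0.0, base - cv_accuracy(d.with_features(rest)))
        total = sum(drops.values())
        if total == 0:
            return {f: 1.0 / len(drops) for f in drops}
        return {f: v / total for f, v in drops.items()}

    star = surrogate_target + "*"
    index = [f for f in features if f != surrogate_target] + [surrogate_target, star]

    original = removal_column(data)
    original[star] = 0.0

    est_frame = data.frame.copy()
    est_frame[star] = oof_surrogate(
        data, target=surrogate_target, k=surrogate_k, folds=k, seed=seed
    )
    est_features = tuple(f if f != surrogate_target else star for f in features)
    est_data = LabeledDataset(
        frame=est_frame, labels=data.y, feature_names=est_features
    )
    estimated = removal_column(est_data)
    estimated[surrogate_target] = 0.0

    predictors = tuple(f for f in features if f != surrogate_target)
    r2_full = surrogate_quality(
        data, target=surrogate_target, k=surrogate_k, folds=k, seed=seed,
        predictors=predictors,
    )
    surrogate_drops = {}
    for f in predictors:
        rest = tuple(g for g in predictors if g != f)
        r2 = surrogate_quality(
            data, target=surrogate_target, k=surrogate_k, folds=k, seed=seed,
            predictors=rest,
        )
        surrogate_drops[f] = max(0.0, r2_full - r2)
    total = sum(surrogate_drops.values())
    if total == 0:
        surrogate_drops = {f: 1.0 / len(predictors) for f in predictors}
    else:
        surrogate_drops = {f: v / total for f, v in surrogate_drops.items()}

    core = {f: estimated.get(f, 0.0) for f in predictors}
    star_mass = estimated.get(star, 0.0)
    for f in predictors:
        core[f] += star_mass * surrogate_drops[f]
    core[surrogate_target] = 0.0
    core[star] = 0.0
    total = sum(core.values())
    core = {f: v / total for f, v in core.items()}

    table = pd.DataFrame(
        {
            "original": [original.get(f, 0.0) for f in index],
            "estimated": [estimated.get(f, 0.0) for f in index],
            "core": [core.get(f, 0.0) for f in index],
        },
        index=index,
    )
    return ImportanceTable(table=table)
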