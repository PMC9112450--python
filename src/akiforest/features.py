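"""Greedy forward feature selection and the ischemia-time surrogate.

Ischemia time (IT) is the strongest surgical predictor of post-operative
kidney injury but is only known after surgery. The surrogate IT* estimates
it pre-operatively with distance-weighted k-nearest neighbors (k=5 default)
over the seven pre-operative features, standardized to zero mean / unit
variance on the training folds (mixed units — cm, years, mg/dL — make raw
Euclidean distance meaningless). Because inverse-distance weighting yields
a convex combination of neighbor targets, IT* always lies within the
observed training IT range, and an exact-match query returns that record's
own IT.

Feature selection adds, at each step, the candidate that maximizes the
evaluator's cross-validated accuracy, and stops when the best gain drops
below ``min_gain`` (absolute accuracy points; "less than 1%" = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import StandardScaler

from .forest import HyperParams, fit_forest
from .records import LabeledDataset, PatientRecord

Evaluator = Callable[[LabeledDataset, int], float]

#: Small fixed-hyper-parameter forest used to score candidate subsets.
SELECTION_HYPER = HyperParams(depth=3, MSPL=1, LC=8, n=25)


@dataclass(frozen=True)
class FeatureSubset:
    features: tuple[str, ...]
    accuracy_trace: tuple[float, ...]  # accuracy after each accepted feature

    def __post_init__(self) -> None:
        if len(self.features) != len(self.accuracy_trace):
            raise ValueError("one accuracy per accepted feature required")


def default_evaluator(data: LabeledDataset, seed: int) -> float:
    """Fivefold-CV accuracy of a small fixed forest on the given features."""
    from .evaluate import kfold_cv  # local import to avoid a cycle

    result = kfold_cv(
        data,
        builder=lambda d, s: fit_forest(d, SELECTION_HYPER, seed=s),
        k=5,
        seed=seed,
    )
    return result.accuracy_mean


def greedy_select(
    data: LabeledDataset,
    candidates: Iterable[str],
    evaluator: Evaluator | None = None,
    min_gain: float = 0.01,
    seed: int = 0,
) -> FeatureSubset:
    """Forward selection with an absolute-gain stopping rule.

    The first pick is always kept; afterwards a feature is accepted only if
    it raises accuracy by at least ``min_gain``. Ties between equally good
    candidates break lexicographically, so the result is deterministic for a
    fixed seed.
    """
    remaining = sorted(set(candidates))
    if not remaining:
        raise ValueError("candidate feature set is empty")
    evaluator = evaluator or default_evaluator
    selected: list[str] = []
    trace: list[float] = []
    current = -np.inf
    while remaining:
        best_feat, best_acc = None, -np.inf
        for feat in remaining:  # lexicographic order; strict > keeps first tie
            acc = evaluator(data.with_features(selected + [feat]), seed)
            if acc > best_acc:
                best_feat, best_acc = feat, acc
        assert best_feat is not None
        if selected and best_acc - current < min_gain:
            break
        selected.append(best_feat)
        remaining.remove(best_feat)
        trace.append(best_acc)
        current = best_acc
    return FeatureSubset(features=tuple(selected), accuracy_trace=tuple(trace))


# ---------------------------------------------------------------------------
# KNN surrogate for ischemia time
# ---------------------------------------------------------------------------

@dataclass
class SurrogateModel:
    target: str
    predictors: tuple[str, ...]
    k: int
    weighting: str
    scaler: StandardScaler
    knn: KNeighborsRegressor
    target_range: tuple[float, float]

    def predict_frame(self, X: np.ndarray) -> np.ndarray:
        """Predict the target for rows given in predictor order."""
        return self.knn.predict(self.scaler.transform(np.asarray(X, dtype=float)))

    def predict_record(self, record: Mapping[str, float] | PatientRecord) -> float:
        values = record.as_dict() if isinstance(record, PatientRecord) else record
        row = np.array([[values[f] for f in self.predictors]], dtype=float)
        return float(self.predict_frame(row)[0])


def fit_surrogate(
    data: LabeledDataset,
    target: str = "IT",
    k: int = 5,
    weighting: str = "distance",
    predictors: Sequence[str] | None = None,
) -> SurrogateModel:
    """Fit the distance-weighted KNN estimator of ``target``."""
    if target not in data.frame.columns:
        raise ValueError(f"target feature {target!r} absent from the data")
    if k > len(data):
        raise ValueError(f"k={k} exceeds the {len(data)} training records")
    if predictors is None:
        predictors = tuple(f for f in data.feature_names if f != target)
    X = data.frame.loc[:, list(predictors)].to_numpy(dtype=float)
    y = data.frame[target].to_numpy(dtype=float)
    scaler = StandardScaler().fit(X)
    knn = KNeighborsRegressor(n_neighbors=k, weights=weighting, metric="euclidean")
    knn.fit(scaler.transform(X), y)
    return SurrogateModel(
        target=target,
        predictors=tuple(predictors),
        k=k,
        weighting=weighting,
        scaler=scaler,
        knn=knn,
        target_range=(float(y.min()), float(y.max())),
    )


def apply_surrogate(
    model: SurrogateModel,
    record: PatientRecord,
    overwrite: bool = False,
) -> PatientRecord:
    """Fill in the surrogate value when the target is absent.

    Records that carry an observed value pass through unchanged unless
    ``overwrite`` is set.
    """
    observed = getattr(record, model.target, None)
    if observed is not None and not overwrite:
        return record
    return record.with_values(**{model.target: model.predict_record(record)})


def oof_surrogate(
    data: LabeledDataset,
    target: str = "IT",
    k: int = 5,
    weighting: str = "distance",
    folds: int = 5,
    seed: int = 0,
    predictors: Sequence[str] | None = None,
) -> np.ndarray:
    """Out-of-fold surrogate predictions for every record."""
    n = len(data)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds the {n} records")
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    out = np.empty(n, dtype=float)
    for train_idx, test_idx in splitter.split(np.arange(n)):
        model = fit_surrogate(
            data.subset(train_idx), target=target, k=k, weighting=weighting,
            predictors=predictors,
        )
        X_test = data.frame.iloc[test_idx].loc[:, list(model.predictors)].to_numpy(dtype=float)
        out[test_idx] = model.predict_frame(X_test)
    return out


def surrogate_quality(
    data: LabeledDataset,
    target: str = "IT",
    k: int = 5,
    weighting: str = "distance",
    folds: int = 5,
    seed: int = 0,
    predictors: Sequence[str] | None = None,
) -> float:
    """Coefficient of determination of OLS of the target on its out-of-fold
    surrogate — how much of the true IT the pre-operative estimate explains."""
    estimates = oof_surrogate(
        data, target=target, k=k, weighting=weighting, folds=folds, seed=seed,
        predictors=predictors,
    )
    truth = data.frame[target].to_numpy(dtype=float)
    slope = stats.linregress(estimates, truth)
    return float(slope.rvalue ** 2)


def tune_surrogate(
    data: LabeledDataset,
    target: str = "IT",
    ks: Sequence[int] = tuple(range(1, 16)),
    weightings: Sequence[str] = ("uniform", "distance"),
    folds: int = 5,
    seed: int = 0,
) -> tuple[int, str, float]:
    """Grid search (k, weighting) by fivefold R²; returns the best triple."""
    best = None
    for weighting in weightings:
        for k in ks:
            if k > len(data) * (folds - 1) // folds:
                continue
            r2 = surrogate_quality(
                data, target=target, k=k, weighting=weighting, folds=folds, seed=seed
            )
            key = (-r2, k, weighting)
            if best is None or key < best[0]:
                best = (key, (k, weighting, r2))
    if best is None:
        raise ValueError("no feasible (k, weighting) combination for this data")
    return best[1]
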