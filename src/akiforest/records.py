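"""Patient records and labeled cohorts.

The modelling feature space consists of eight pre-/peri-operative variables
commonly recorded before open partial nephrectomy:

========== =============================================== ========
name       meaning                                         unit
========== =============================================== ========
size       tumor diameter                                  cm
renal      RENAL nephrometry score (integer 4-12)          --
age        patient age at surgery                          yr
baseHB     baseline hemoglobin                             g/dL
IT         renal-artery ischemia time (surgical; may be
           absent pre-operatively)                         min
weight     body weight                                     kg
height     body height                                     cm
creatinine baseline serum creatinine                       mg/dL
========== =============================================== ========

A :class:`LabeledDataset` is a thin wrapper around a pandas DataFrame: the
frame may carry extra demographic columns (gender, smoking) used only for
cohort balancing, while ``feature_names`` selects the modelling features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical modelling features, in the conventional order.
FEATURES: tuple[str, ...] = (
    "size",
    "renal",
    "age",
    "baseHB",
    "IT",
    "weight",
    "height",
    "creatinine",
)

#: Features available strictly before surgery (everything but ischemia time).
PREOP_FEATURES: tuple[str, ...] = tuple(f for f in FEATURES if f != "IT")

LABEL_COLUMN = "aki"


@dataclass(frozen=True)
class PatientRecord:
    """One patient's modelling features.

    ``IT`` may be ``None`` at prediction time; the KNN surrogate fills it in.
    """

    size: float
    renal: float
    age: float
    baseHB: float
    weight: float
    height: float
    creatinine: float
    IT: float | None = None

    def __post_init__(self) -> None:
        for name in FEATURES:
            v = getattr(self, name)
            if v is None:
                if name == "IT":
                    continue
                raise ValueError(f"feature {name!r} is required")
            if not np.isfinite(v):
                raise ValueError(f"feature {name!r} must be finite, got {v!r}")
        if self.size <= 0:
            raise ValueError(f"tumor size must be positive, got {self.size}")
        if self.age <= 18:
            raise ValueError(f"age must exceed 18 yr, got {self.age}")
        if self.creatinine <= 0:
            raise ValueError(f"baseline creatinine must be positive, got {self.creatinine}")

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in FEATURES}
        return {k: v for k, v in d.items() if v is not None}

    def with_values(self, **updates: float) -> "PatientRecord":
        d = {name: getattr(self, name) for name in FEATURES}
        d.update(updates)
        return PatientRecord(**d)


@dataclass
class LabeledDataset:
    """Feature frame + binary AKI labels (AKI=1 / non-AKI=0).

    ``frame`` may contain columns beyond ``feature_names`` (e.g. ``gender``,
    ``smoking`` for split balancing); modelling code only ever touches the
    named features.
    """

    frame: pd.DataFrame
    labels: np.ndarray
    feature_names: tuple[str, ...]
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.frame) != len(self.labels):
            raise ValueError(
                f"{len(self.frame)} records but {len(self.labels)} labels"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        missing = [f for f in self.feature_names if f not in self.frame.columns]
        if missing:
            raise ValueError(f"features absent from frame: {missing}")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary 0/1, found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame.loc[:, list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def subset(self, indices: Sequence[int] | np.ndarray) -> "LabeledDataset":
        idx = np.asarray(indices)
        return LabeledDataset(
            frame=self.frame.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            feature_names=self.feature_names,
            extra=dict(self.extra),
        )

    def with_features(self, feature_names: Iterable[str]) -> "LabeledDataset":
        return LabeledDataset(
            frame=self.frame,
            labels=self.labels,
            feature_names=tuple(feature_names),
            extra=dict(self.extra),
        )

    def records(self) -> list[dict[str, float]]:
        """Rows as feature dicts (modelling features only)."""
        return self.frame.loc[:, list(self.feature_names)].to_dict("records")


def dataset_from_arrays(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
) -> LabeledDataset:
    frame = pd.DataFrame(np.asarray(X, dtype=float), columns=list(feature_names))
    return LabeledDataset(frame=frame, labels=np.asarray(y), feature_names=tuple(feature_names))


def read_patients_csv(path: str | Path, feature_names: Sequence[str] = FEATURES) -> LabeledDataset:
    """Read the standard patients CSV (one row per patient, optional ``aki`` column)."""
    frame = pd.read_csv(path)
    missing = [f for f in feature_names if f not in frame.columns]
    if missing:
        raise ValueError(f"patients CSV {path} lacks columns: {missing}")
    if LABEL_COLUMN in frame.columns:
        labels = frame[LABEL_COLUMN].to_numpy(dtype=int)
    else:
        labels = np.zeros(len(frame), dtype=int)
    return LabeledDataset(frame=frame, labels=labels, feature_names=tuple(feature_names))


def write_patients_csv(data: LabeledDataset, path: str | Path) -> None:
    out = data.frame.copy()
    out[LABEL_COLUMN] = data.labels
    out.to_csv(path, index=False)


def record_from_mapping(values: Mapping[str, float]) -> PatientRecord:
    known = {k: v for k, v in values.items() if k in FEATURES}
    return PatientRecord(**known)
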