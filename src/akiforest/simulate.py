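"""Synthetic partial-nephrectomy cohorts.

Generates patient tables with the statistical structure an open-PN AKI
cohort exhibits, so every stage of the pipeline is testable without patient
data: a Gaussian copula imposes the reported feature correlations (RENAL
score vs tumor size 0.57, height vs weight 0.45, everything else near
zero), marginals are truncated normals (the RENAL score discretized to its
integer 4-12 range), ischemia time is a linear function of size, RENAL
score and age plus Gaussian noise (so the KNN surrogate's R² has the closed
form signalVar / (signalVar + noiseVar)), and the binary AKI outcome comes
from a logistic model whose intercept is calibrated to the target
prevalence 231/723 ≈ 0.32.

Cohort-level defaults (n = 723, age 61.23 ± 12.05 yr, 17.6% smokers, 62%
female, ~32% AKI) mirror the published cohort summary; the remaining
marginals are plausible clinical values and documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .boolmin import DNF
from .labeling import CRITERIA, AKILabel, CreatinineSeries, label_aki
from .records import FEATURES, LabeledDataset

#: truncated-normal marginals: (mean, sd, lower, upper)
DEFAULT_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "size": (3.5, 1.8, 0.5, 12.0),
    "renal": (7.5, 2.0, 4.0, 12.0),   # discretized to integers 4..12
    "age": (61.23, 12.05, 19.0, 95.0),
    "baseHB": (13.3, 1.7, 7.0, 18.5),
    "weight": (78.0, 14.0, 45.0, 140.0),
    "height": (167.0, 10.0, 140.0, 200.0),
    "creatinine": (1.05, 0.30, 0.4, 3.0),
}

#: IT (minutes) = intercept + dot(coeffs, [size, renal, age]) + noise
IT_COEFFS: dict[str, float] = {"size": 4.0, "renal": 1.5, "age": 0.05}
IT_INTERCEPT = 2.0

#: logistic outcome coefficients on standardized features
DEFAULT_OUTCOME_COEFFS: dict[str, float] = {
    "size": 0.8,
    "renal": 0.5,
    "age": 0.5,
    "baseHB": -0.4,
    "IT": 0.9,
    "weight": 0.15,
    "height": -0.1,
    "creatinine": 0.7,
}


@dataclass(frozen=True)
class CohortSpec:
    """Everything the cohort generator needs, with study-level defaults."""

    n: int = 723
    seed: int = 0
    marginals: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    smoking_prevalence: float = 0.176
    female_fraction: float = 0.62
    corr_renal_size: float = 0.57
    corr_height_weight: float = 0.45
    aki_prevalence: float = 231 / 723
    it_noise_ratio: float = 0.35  # noise SD as a fraction of the IT signal SD
    outcome_coeffs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFS)
    )

    def __post_init__(self) -> None:
        if not 0 < self.aki_prevalence < 1:
            raise ValueError(f"AKI prevalence must lie in (0,1), got {self.aki_prevalence}")

    def correlation_matrix(self, columns: Sequence[str]) -> np.ndarray:
        corr = np.eye(len(columns))
        pairs = {
            ("renal", "size"): self.corr_renal_size,
            ("height", "weight"): self.corr_height_weight,
        }
        idx = {c: i for i, c in enumerate(columns)}
        for (a, b), r in pairs.items():
            if a in idx and b in idx:
                corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("correlation targets give a non-positive-definite matrix")
        return corr


def generate_cohort(spec: CohortSpec | None = None, **overrides) -> LabeledDataset:
    """Draw a labeled synthetic cohort; bit-deterministic given the seed."""
    spec = replace(spec or CohortSpec(), **overrides) if overrides else (spec or CohortSpec())
    rng = np.random.default_rng(spec.seed)
    copula_cols = list(spec.marginals) + ["smoking", "gender"]
    corr = spec.correlation_matrix(copula_cols)
    z = rng.multivariate_normal(np.zeros(len(copula_cols)), corr, size=spec.n,
                                method="cholesky")
    u = stats.norm.cdf(z)

    frame = pd.DataFrame(index=range(spec.n))
    for j, col in enumerate(copula_cols):
        if col == "smoking":
            frame[col] = (u[:, j] < spec.smoking_prevalence).astype(int)
        elif col == "gender":  # 1 = female
            frame[col] = (u[:, j] < spec.female_fraction).astype(int)
        else:
            mean, sd, lo, hi = spec.marginals[col]
            a, b = (lo - mean) / sd, (hi - mean) / sd
            vals = stats.truncnorm.ppf(u[:, j], a, b, loc=mean, scale=sd)
            if col == "renal":
                vals = np.clip(np.rint(vals), 4, 12)
            frame[col] = vals

    signal = IT_INTERCEPT + sum(c * frame[f].to_numpy() for f, c in IT_COEFFS.items())
    noise_sd = spec.it_noise_ratio * float(np.std(signal))
    frame["IT"] = signal + rng.normal(0.0, noise_sd, size=spec.n)

    X = frame.loc[:, list(FEATURES)].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    beta = np.array([spec.outcome_coeffs.get(f, 0.0) for f in FEATURES])
    lp = (X - mu) / sd @ beta

    def excess(intercept: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(intercept + lp))))) - spec.aki_prevalence

    intercept = optimize.brentq(excess, -20.0, 20.0)
    p = 1.0 / (1.0 + np.exp(-(intercept + lp)))
    labels = (rng.random(spec.n) < p).astype(int)

    return LabeledDataset(
        frame=frame,
        labels=labels,
        feature_names=FEATURES,
        extra={"spec": spec, "logit_intercept": intercept},
    )


def generate_planted_rule_cohort(
    n: int,
    rule: DNF,
    noise: float = 0.0,
    seed: int = 0,
    values: Mapping[str, Sequence[float]] | None = None,
    features: Sequence[str] | None = None,
) -> LabeledDataset:
    """Cohort whose label is a known DNF rule, XOR-ed with flip noise.

    By default each feature is drawn uniformly from a half-integer lattice
    (0.5, 1.5, ..., 9.5), so integer rule thresholds fall exactly midway
    between adjacent observed values and a tree fit on the cohort recovers
    them verbatim. ``values`` overrides the lattice per feature.
    """
    if not 0 <= noise < 0.5:
        raise ValueError(f"flip noise must lie in [0, 0.5), got {noise}")
    rng = np.random.default_rng(seed)
    feats = tuple(features) if features is not None else tuple(
        sorted({f for t in rule.terms for f, _, _ in t.intervals})
    )
    default_lattice = np.arange(0.5, 10.0, 1.0)
    frame = pd.DataFrame({
        f: rng.choice(np.asarray((values or {}).get(f, default_lattice), dtype=float), size=n)
        for f in feats
    })
    truth = np.array(
        [rule.satisfied_by(row) for row in frame.to_dict("records")], dtype=int
    )
    flips = rng.random(n) < noise
    labels = truth ^ flips
    return LabeledDataset(
        frame=frame,
        labels=labels,
        feature_names=feats,
        extra={"rule": rule, "true_labels": truth, "noise": noise},
    )


def generate_creatinine_series(
    n: int,
    aki_fraction: float,
    seed: int = 0,
    criterion: str | None = None,
) -> list[tuple[CreatinineSeries, AKILabel]]:
    """Creatinine-series fixtures with known ground-truth AKI labels.

    Positives are constructed to fire exactly one chosen criterion (cycling
    through the three when ``criterion`` is None); negatives stay strictly
    below every threshold. Construction is verified against
    :func:`~akiforest.labeling.label_aki` before returning.
    """
    if criterion is not None and criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * aki_fraction))
    out: list[tuple[CreatinineSeries, AKILabel]] = []
    for i in range(n):
        age = float(rng.uniform(30, 80))
        sex = "female" if rng.random() < 0.5 else "male"
        pid = f"synth-{i:04d}"
        if i < n_pos:
            crit = criterion or CRITERIA[i % 3]
            if crit == "relative_rise":
                # low baseline keeps the eGFR ratio above 0.75 and the
                # absolute rise below 0.3 mg/dL; hour > 48 avoids criterion 2
                base = float(rng.uniform(0.35, 0.45))
                series = CreatinineSeries(
                    baseline=base,
                    measurements=((120.0, 1.5 * base + 0.01),),
                    age=age, sex=sex, patient_id=pid,
                )
                truth = AKILabel(True, frozenset({"relative_rise"}))
            elif crit == "absolute_rise_48h":
                # high baseline: +0.3 is a small relative rise, eGFR holds
                base = float(rng.uniform(1.5, 1.8))
                series = CreatinineSeries(
                    baseline=base,
                    measurements=((24.0, base + 0.31),),
                    age=age, sex=sex, patient_id=pid,
                )
                truth = AKILabel(True, frozenset({"absolute_rise_48h"}))
            else:  # egfr_drop: ratio ~1.3 after the 48 h window
                base = float(rng.uniform(1.0, 1.2))
                series = CreatinineSeries(
                    baseline=base,
                    measurements=((24.0, base + 0.05), (120.0, 1.32 * base)),
                    age=age, sex=sex, patient_id=pid,
                )
                truth = AKILabel(True, frozenset({"egfr_drop"}))
        else:
            base = float(rng.uniform(0.8, 1.2))
            series = CreatinineSeries(
                baseline=base,
                measurements=((24.0, base * 1.05), (72.0, base * 1.10)),
                age=age, sex=sex, patient_id=pid,
            )
            truth = AKILabel(False, frozenset())
        assert label_aki(series) == truth, "fixture construction violated a threshold"
        out.append((series, truth))
    return out
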