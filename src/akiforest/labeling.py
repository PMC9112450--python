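"""Binary AKI labeling from serial post-operative serum creatinine.

A patient is labeled AKI-positive when at least one of three consensus
(RIFLE/AKIN-style) conditions holds relative to the pre-operative baseline:

1. ``relative_rise`` — serum creatinine reaches >= 1.5 x baseline within the
   first post-operative week (168 h, inclusive);
2. ``absolute_rise_48h`` — creatinine rises by >= 0.3 mg/dL (26.5 µmol/L)
   above baseline within 48 h (inclusive);
3. ``egfr_drop`` — estimated GFR falls more than 25% below the baseline eGFR
   within the first week.

eGFR defaults to CKD-EPI 2009 (race coefficient omitted); MDRD-4 is
selectable. The ``relative_rise`` reading of "0.5 times above baseline" is
the multiplicative one (x1.5, the RIFLE Risk class); an additive
+0.5 mg/dL reading is available via ``relative_mode="additive"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

MG_DL_PER_UMOL_L = 1.0 / 88.42  # 88.42 µmol/L per mg/dL

WEEK_HOURS = 168.0
WINDOW_48H = 48.0
RELATIVE_FACTOR = 1.5
ABSOLUTE_RISE_MG_DL = 0.3
EGFR_DROP_FRACTION = 0.25

CRITERIA = ("relative_rise", "absolute_rise_48h", "egfr_drop")


def egfr(creatinine: float, age: float, sex: str, formula: str = "ckd-epi") -> float:
    """Estimated glomerular filtration rate, mL/min/1.73 m².

    ``formula``: ``"ckd-epi"`` (2009, no race coefficient) or ``"mdrd"``
    (4-variable MDRD). Strictly decreasing in creatinine at fixed
    demographics.
    """
    if creatinine <= 0:
        raise ValueError(f"creatinine must be positive, got {creatinine}")
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    sex = sex.lower()
    if sex not in ("male", "female", "m", "f"):
        raise ValueError(f"sex must be male/female, got {sex!r}")
    female = sex in ("female", "f")
    formula = formula.lower()
    if formula == "ckd-epi":
        kappa = 0.7 if female else 0.9
        alpha = -0.329 if female else -0.411
        ratio = creatinine / kappa
        value = (
            141.0
            * min(ratio, 1.0) ** alpha
            * max(ratio, 1.0) ** -1.209
            * 0.993 ** age
        )
        if female:
            value *= 1.018
        return value
    if formula == "mdrd":
        value = 175.0 * creatinine ** -1.154 * age ** -0.203
        if female:
            value *= 0.742
        return value
    raise ValueError(f"unknown eGFR formula {formula!r}; use 'ckd-epi' or 'mdrd'")


@dataclass(frozen=True)
class CreatinineSeries:
    """Baseline + timestamped post-operative creatinine for one patient.

    ``measurements`` are ``(hours since surgery, sCr)`` pairs, strictly
    increasing in time. ``unit`` is ``"mg/dL"`` (default) or ``"umol/L"``;
    µmol/L inputs are interpreted via the 88.42 conversion factor.
    """

    baseline: float
    measurements: tuple[tuple[float, float], ...]
    age: float
    sex: str
    unit: str = "mg/dL"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.unit not in ("mg/dL", "umol/L"):
            raise ValueError(f"unit must be 'mg/dL' or 'umol/L', got {self.unit!r}")
        if self.baseline <= 0:
            raise ValueError(f"baseline creatinine must be positive, got {self.baseline}")
        hours = [h for h, _ in self.measurements]
        if any(h < 0 for h in hours):
            raise ValueError("measurement hours must be non-negative")
        if any(h2 <= h1 for h1, h2 in zip(hours, hours[1:])):
            raise ValueError("measurement hours must be strictly increasing")
        if any(v <= 0 for _, v in self.measurements):
            raise ValueError("all creatinine values must be positive")

    def in_mg_dl(self) -> "CreatinineSeries":
        if self.unit == "mg/dL":
            return self
        f = MG_DL_PER_UMOL_L
        return CreatinineSeries(
            baseline=self.baseline * f,
            measurements=tuple((h, v * f) for h, v in self.measurements),
            age=self.age,
            sex=self.sex,
            unit="mg/dL",
            patient_id=self.patient_id,
        )


@dataclass(frozen=True)
class AKILabel:
    aki: bool
    criteria_fired: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        assert self.aki == bool(self.criteria_fired)


def label_aki(
    series: CreatinineSeries,
    formula: str = "ckd-epi",
    relative_mode: str = "ratio",
) -> AKILabel:
    """Apply the three-criterion AKI definition to one creatinine series."""
    if not series.measurements:
        raise ValueError(
            f"patient {series.patient_id or '<unnamed>'}: no post-operative "
            "measurements; the series cannot be labeled"
        )
    if relative_mode not in ("ratio", "additive"):
        raise ValueError(f"relative_mode must be 'ratio' or 'additive', got {relative_mode!r}")
    s = series.in_mg_dl()
    fired: set[str] = set()
    base_egfr = egfr(s.baseline, s.age, s.sex, formula=formula)
    for hours, value in s.measurements:
        if hours <= WEEK_HOURS:
            if relative_mode == "ratio":
                rel = value >= RELATIVE_FACTOR * s.baseline
            else:
                rel = value - s.baseline >= 0.5
            if rel:
                fired.add("relative_rise")
            if egfr(value, s.age, s.sex, formula=formula) < (1 - EGFR_DROP_FRACTION) * base_egfr:
                fired.add("egfr_drop")
        if hours <= WINDOW_48H and value - s.baseline >= ABSOLUTE_RISE_MG_DL - 1e-12:
            fired.add("absolute_rise_48h")
    return AKILabel(aki=bool(fired), criteria_fired=frozenset(fired))


def label_many(
    series: Sequence[CreatinineSeries],
    formula: str = "ckd-epi",
    relative_mode: str = "ratio",
) -> list[AKILabel]:
    return [label_aki(s, formula=formula, relative_mode=relative_mode) for s in series]
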