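"""CURB65, ProADM and CURB65-A classification rules.

The CURB65 score awards one point each for Confusion, Urea > 7 mmol/L,
Respiratory rate >= 30/min, low Blood pressure (systolic < 90 mmHg or
diastolic <= 60 mmHg) and age >= 65 years, giving a 0-5 severity score
that is conventionally collapsed into three risk classes (0-1 / 2 / 3-5).
CURB65-A refines those classes with two proadrenomedullin (ProADM)
cut-offs, 0.75 and 1.5 nmol/L, yielding risk classes I-III and a matching
site-of-care recommendation.

ProADM boundaries are treated as closed on the upper side: a value of
exactly 0.75 nmol/L is "low" and exactly 1.5 nmol/L is "mid". Published
descriptions of the rule alternate between "<0.75" and "<=0.75"; the
closed-upper convention matches the rule as stated in full and is the one
implemented and tested here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Curb65Class",
    "ProAdmCategory",
    "RiskClass",
    "TriageRecommendation",
    "ScoreThresholds",
    "PatientRecord",
    "MissingDataError",
    "curb65_score",
    "curb65_class",
    "proadm_category",
    "curb65a_class",
    "triage_recommendation",
    "classify_patient",
    "curb65_score_array",
    "score_cohort_frame",
]


class MissingDataError(ValueError):
    """A CURB65 component needed for scoring is absent."""


class Curb65Class(enum.IntEnum):
    """Conventional CURB65 risk classes: scores 0-1, 2, and 3-5."""

    LOW = 0
    MID = 1
    HIGH = 2


class ProAdmCategory(enum.IntEnum):
    """ProADM strata: <=0.75, (0.75, 1.5], and >1.5 nmol/L."""

    LOW = 0
    MID = 1
    HIGH = 2


class RiskClass(enum.IntEnum):
    """CURB65-A composite risk class."""

    I = 1
    II = 2
    III = 3


class TriageRecommendation(enum.Enum):
    OUTPATIENT = "outpatient"
    SHORT_HOSPITALIZATION = "short_hospitalization"
    INPATIENT = "inpatient"


@dataclass(frozen=True)
class ScoreThresholds:
    """Component cut-offs for CURB65 and the ProADM category boundaries.

    CURB65 components follow Lim et al.'s original definition; ProADM
    boundaries are the two cut-offs of the composite rule (nmol/L).
    """

    curb65_urea_gt: float = 7.0
    curb65_rr_ge: float = 30.0
    curb65_sbp_lt: float = 90.0
    curb65_dbp_le: float = 60.0
    curb65_age_ge: float = 65.0
    proadm_low_max: float = 0.75
    proadm_mid_max: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.proadm_low_max < self.proadm_mid_max:
            raise ValueError(
                "ProADM boundaries must satisfy 0 < low_max < mid_max, got "
                f"{self.proadm_low_max} and {self.proadm_mid_max}"
            )


DEFAULT_THRESHOLDS = ScoreThresholds()

PROADM_DETECTION_LIMIT = 0.08  # nmol/L, assay analytical detection limit


class Diagnosis(enum.Enum):
    CAP = "CAP"
    COPD_EXACERBATION = "COPD_exacerbation"
    BRONCHITIS = "bronchitis"
    OTHER = "other"


@dataclass
class PatientRecord:
    """One subject: admission covariates, ProADM, diagnosis, 30-day outcomes.

    ``outpatient`` means discharge from hospital or emergency department
    after one day or less.
    """

    age: int
    confusion: bool
    urea: Optional[float]  # mmol/L; may be missing in real-world tables
    resp_rate: int
    sbp: float
    dbp: float
    proadm: float  # nmol/L
    diagnosis: Diagnosis
    death30: bool
    icu30: bool
    complication30: bool
    outpatient: bool

    def validate(self) -> None:
        if self.age < 18:
            raise ValueError(f"age must be >= 18, got {self.age}")
        if self.resp_rate <= 0:
            raise ValueError(f"resp_rate must be positive, got {self.resp_rate}")
        if self.sbp <= 0 or self.dbp <= 0:
            raise ValueError(f"blood pressure must be positive, got {self.sbp}/{self.dbp}")
        if self.urea is not None and not math.isnan(self.urea) and self.urea < 0:
            raise ValueError(f"urea must be nonnegative, got {self.urea}")
        if not self.proadm >= PROADM_DETECTION_LIMIT:
            raise ValueError(
                f"proadm must be >= {PROADM_DETECTION_LIMIT} nmol/L "
                f"(assay detection limit), got {self.proadm}"
            )

    @property
    def adverse_event(self) -> bool:
        """Composite 30-day endpoint: death, ICU admission or complication."""
        return self.death30 or self.icu30 or self.complication30


def _require(value, field: str):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingDataError(f"CURB65 component '{field}' is missing")
    return value


def curb65_score(p: PatientRecord, t: ScoreThresholds = DEFAULT_THRESHOLDS) -> int:
    """Compute the 0-5 CURB65 score; missing components raise MissingDataError."""
    urea = _require(p.urea, "urea")
    confusion = _require(p.confusion, "confusion")
    rr = _require(p.resp_rate, "resp_rate")
    sbp = _require(p.sbp, "sbp")
    dbp = _require(p.dbp, "dbp")
    age = _require(p.age, "age")
    return int(
        bool(confusion)
        + (urea > t.curb65_urea_gt)
        + (rr >= t.curb65_rr_ge)
        + (sbp < t.curb65_sbp_lt or dbp <= t.curb65_dbp_le)
        + (age >= t.curb65_age_ge)
    )


def curb65_class(score: int) -> Curb65Class:
    """Collapse a CURB65 score into the low / intermediate / high class."""
    if not 0 <= score <= 5:
        raise ValueError(f"CURB65 score must be in 0..5, got {score}")
    if score <= 1:
        return Curb65Class.LOW
    if score == 2:
        return Curb65Class.MID
    return Curb65Class.HIGH


def proadm_category(
    proadm: float, t: ScoreThresholds = DEFAULT_THRESHOLDS
) -> ProAdmCategory:
    """Assign the ProADM stratum; boundaries belong to the lower stratum."""
    if not proadm > 0:
        raise ValueError(f"proadm must be positive, got {proadm}")
    if proadm <= t.proadm_low_max:
        return ProAdmCategory.LOW
    if proadm <= t.proadm_mid_max:
        return ProAdmCategory.MID
    return ProAdmCategory.HIGH


# (Curb65Class, ProAdmCategory) -> RiskClass. Class I is the single
# low/low cell; class II is CURB65 2 with ProADM <= 1.5 or CURB65 0-1 with
# ProADM in (0.75, 1.5]; every other cell is class III.
_CURB65A_GRID = {
    (Curb65Class.LOW, ProAdmCategory.LOW): RiskClass.I,
    (Curb65Class.LOW, ProAdmCategory.MID): RiskClass.II,
    (Curb65Class.MID, ProAdmCategory.LOW): RiskClass.II,
    (Curb65Class.MID, ProAdmCategory.MID): RiskClass.II,
}


def curb65a_class(c: Curb65Class, a: ProAdmCategory) -> RiskClass:
    """Combine a CURB65 class and a ProADM category into CURB65-A class I-III."""
    return _CURB65A_GRID.get((Curb65Class(c), ProAdmCategory(a)), RiskClass.III)


_TRIAGE = {
    RiskClass.I: TriageRecommendation.OUTPATIENT,
    RiskClass.II: TriageRecommendation.SHORT_HOSPITALIZATION,
    RiskClass.III: TriageRecommendation.INPATIENT,
}


def triage_recommendation(r: RiskClass) -> TriageRecommendation:
    """Site-of-care recommendation attached to each CURB65-A class."""
    return _TRIAGE[RiskClass(r)]


def classify_patient(
    p: PatientRecord, t: ScoreThresholds = DEFAULT_THRESHOLDS
) -> tuple[int, Curb65Class, ProAdmCategory, RiskClass, TriageRecommendation]:
    """Run the full classification chain for one patient."""
    score = curb65_score(p, t)
    c = curb65_class(score)
    a = proadm_category(p.proadm, t)
    r = curb65a_class(c, a)
    return score, c, a, r, triage_recommendation(r)


def curb65_score_array(
    age: np.ndarray,
    confusion: np.ndarray,
    urea: np.ndarray,
    resp_rate: np.ndarray,
    sbp: np.ndarray,
    dbp: np.ndarray,
    t: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Vectorized CURB65 score over aligned covariate arrays."""
    urea = np.asarray(urea, dtype=float)
    if np.isnan(urea).any():
        raise MissingDataError("CURB65 component 'urea' is missing")
    return (
        np.asarray(confusion, dtype=bool).astype(int)
        + (urea > t.curb65_urea_gt)
        + (np.asarray(resp_rate) >= t.curb65_rr_ge)
        + ((np.asarray(sbp) < t.curb65_sbp_lt) | (np.asarray(dbp) <= t.curb65_dbp_le))
        + (np.asarray(age) >= t.curb65_age_ge)
    )


def score_cohort_frame(
    df: pd.DataFrame, t: ScoreThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Augment a cohort table with scoring columns.

    Adds ``curb65``, ``curb65_class``, ``proadm_cat``, ``riskclass`` and
    ``recommendation`` to a copy of ``df`` (cohort CSV schema columns).
    """
    out = df.copy()
    score = curb65_score_array(
        out["age"].to_numpy(),
        out["confusion"].to_numpy(),
        out["urea_mmol_l"].to_numpy(),
        out["resp_rate"].to_numpy(),
        out["sbp"].to_numpy(),
        out["dbp"].to_numpy(),
        t,
    )
    proadm = out["proadm_nmol_l"].to_numpy(dtype=float)
    if not (proadm > 0).all():
        raise ValueError("proadm_nmol_l must be positive for all rows")
    cat = np.where(proadm <= t.proadm_low_max, 0, np.where(proadm <= t.proadm_mid_max, 1, 2))
    cls = np.where(score <= 1, 0, np.where(score == 2, 1, 2))
    risk = np.full(len(out), 3)
    risk[(cls == 0) & (cat == 0)] = 1
    risk[((cls == 0) & (cat == 1)) | ((cls == 1) & (cat <= 1))] = 2
    out["curb65"] = score
    out["curb65_class"] = cls
    out["proadm_cat"] = cat
    out["riskclass"] = risk
    out["recommendation"] = np.choose(
        risk - 1,
        [
            TriageRecommendation.OUTPATIENT.value,
            TriageRecommendation.SHORT_HOSPITALIZATION.value,
            TriageRecommendation.INPATIENT.value,
        ],
    )
    return out
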