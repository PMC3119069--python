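"""Synthetic LRTI cohort generator.

Emulates the joint structure of a ~1400-patient emergency-department
lower-respiratory-tract-infection cohort: the CURB65 class split
(48.5% / 31.9% / 19.6%), the ProADM category margins (353 / 588 / 418 of
1359), the CURB65-A class sizes (306 / 534 / 519), right-skewed ProADM
with median ~1.1 nmol/L, and class-conditional 30-day adverse-event and
mortality probabilities. Outcomes are driven by the CURB65-A class with an
explicit within-class log-ProADM effect, so within-class trend tests and
calibration analyses are non-degenerate on generated data.

Everything is deterministic given the seed; the same config and seed yield
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import expit

from .scoring import (
    Diagnosis,
    PatientRecord,
    PROADM_DETECTION_LIMIT,
    curb65_score_array,
    score_cohort_frame,
)

__all__ = ["CohortConfig", "CohortConfigError", "generate_cohort", "generate_cohort_frame", "describe_cohort"]


class CohortConfigError(ValueError):
    """The cohort configuration is infeasible or inconsistent."""


# Conditional P(ProADM category | CURB65 class). Row sums, column sums and
# the corner cells are pinned by the published margins (659/434/266 rows,
# 353/588/418 columns, 306 in the low/low cell, 11 in the high/low cell);
# the remaining free cell is set to 250 so the rows are stochastically
# ordered (ProADM shifts upward with CURB65 severity).
_DEFAULT_PROADM_GIVEN_CURB65 = (
    (306 / 659, 250 / 659, 103 / 659),
    (36 / 434, 248 / 434, 150 / 434),
    (11 / 266, 90 / 266, 165 / 266),
)

# Truncated log-normal parameters (mu, sigma on the log scale) per ProADM
# category; supports are the category intervals, with the assay detection
# limit as the global floor.
_DEFAULT_PROADM_LOGNORM = (
    (np.log(0.55), 0.40),
    (np.log(1.05), 0.35),
    (np.log(2.00), 0.55),
)

_PROADM_BOUNDS = ((PROADM_DETECTION_LIMIT, 0.75), (0.75, 1.5), (1.5, np.inf))


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort.

    Defaults reproduce the published marginal and joint structure; event
    probabilities are per CURB65-A class, and ``within_class_proadm_slope``
    (log-odds per log nmol/L) injects the within-class biomarker-risk
    gradient. Outpatient rates per class are calibrated to the published
    site-of-care margins (88/306, 38/534, 16/519).
    """

    n: int = 1359
    seed: int = 0
    curb65_class_probs: tuple = (0.485, 0.319, 0.196)
    proadm_cat_probs_given_curb65: tuple = _DEFAULT_PROADM_GIVEN_CURB65
    proadm_lognormal_params_per_cat: tuple = _DEFAULT_PROADM_LOGNORM
    adverse_probs_per_riskclass: tuple = (0.0392, 0.0861, 0.2158)
    mortality_probs_per_riskclass: tuple = (0.0065, 0.0262, 0.0983)
    within_class_proadm_slope: float = 1.0
    cap_fraction: float = 0.681
    diagnosis_probs: tuple = (0.681, 0.168, 0.111, 0.040)  # CAP/COPD/bronchitis/other
    outpatient_rate_per_riskclass: tuple = (88 / 306, 38 / 534, 16 / 519)

    def validate(self) -> None:
        if self.n < 1:
            raise CohortConfigError("n must be >= 1")
        for name, vec in (
            ("curb65_class_probs", self.curb65_class_probs),
            ("diagnosis_probs", self.diagnosis_probs),
        ):
            v = np.asarray(vec, dtype=float)
            if (v < 0).any() or abs(v.sum() - 1) > 1e-12:
                raise CohortConfigError(f"{name} must be nonnegative and sum to 1")
        mat = np.asarray(self.proadm_cat_probs_given_curb65, dtype=float)
        if mat.shape != (3, 3):
            raise CohortConfigError("proadm_cat_probs_given_curb65 must be 3x3")
        for i in range(3):
            for j in range(3):
                if mat[i, j] < 0:
                    raise CohortConfigError(
                        f"proadm_cat_probs_given_curb65 cell ({i},{j}) is negative: "
                        f"{mat[i, j]:.6g}"
                    )
            if abs(mat[i].sum() - 1) > 1e-12:
                raise CohortConfigError(
                    f"proadm_cat_probs_given_curb65 row {i} must sum to 1"
                )
        adv = np.asarray(self.adverse_probs_per_riskclass, dtype=float)
        mort = np.asarray(self.mortality_probs_per_riskclass, dtype=float)
        for name, v in (("adverse", adv), ("mortality", mort)):
            if (v < 0).any() or (v > 1).any():
                raise CohortConfigError(f"{name} probabilities must lie in [0, 1]")
            if not (v[0] < v[1] < v[2]):
                raise CohortConfigError(
                    f"{name} probabilities must increase across risk classes"
                )
        if (mort > adv).any():
            raise CohortConfigError(
                "mortality probability cannot exceed the adverse-event probability"
            )

    def expected_adverse_rate(self) -> float:
        """Class-size-weighted mean adverse-event probability (analytic)."""
        mat = np.asarray(self.proadm_cat_probs_given_curb65, dtype=float)
        curb = np.asarray(self.curb65_class_probs, dtype=float)
        joint = curb[:, None] * mat
        class_p = np.array(
            [
                joint[0, 0],
                joint[0, 1] + joint[1, 0] + joint[1, 1],
                joint[0, 2] + joint[1, 2] + joint[2].sum(),
            ]
        )
        return float(class_p @ np.asarray(self.adverse_probs_per_riskclass))


# ---------------------------------------------------------------- covariates

# Admission-covariate sampling distributions, chosen to match the published
# baseline table (age median 73, IQR 59-82; RR median 20, IQR 16-25;
# SBP median 134, IQR 120-150; confusion 6.8%) and to give CURB65 component
# prevalences from which every class is reachable by rejection.
_AGE_MU, _AGE_SD = 70.0, 16.0
_CONFUSION_P = 0.068
_UREA_LOGMU, _UREA_LOGSD = np.log(6.0), 0.5
_RR_LOGMU, _RR_LOGSD = np.log(20.0), 0.33
_SBP_MU, _SBP_SD = 134.0, 22.0
_DBP_MU, _DBP_SD = 75.0, 12.0


def _draw_covariates(rng: np.random.Generator, m: int) -> dict:
    age = np.clip(np.rint(rng.normal(_AGE_MU, _AGE_SD, m)), 18, 102).astype(int)
    confusion = rng.random(m) < _CONFUSION_P
    urea = np.maximum(rng.lognormal(_UREA_LOGMU, _UREA_LOGSD, m), 0.5)
    rr = np.clip(np.rint(rng.lognormal(_RR_LOGMU, _RR_LOGSD, m)), 8, 60).astype(int)
    sbp = np.maximum(rng.normal(_SBP_MU, _SBP_SD, m), 60.0)
    dbp = np.maximum(rng.normal(_DBP_MU, _DBP_SD, m), 30.0)
    return {"age": age, "confusion": confusion, "urea": urea, "rr": rr, "sbp": sbp, "dbp": dbp}


def _sample_covariates_for_classes(
    rng: np.random.Generator, target_class: np.ndarray
) -> dict:
    """Rejection-sample covariate sets whose CURB65 class matches the target.

    Draws waves of candidate covariate vectors from the marginal
    distributions, classifies them, and assigns them in draw order to the
    patients still needing that class.
    """
    n = len(target_class)
    out = {
        "age": np.empty(n, dtype=int),
        "confusion": np.empty(n, dtype=bool),
        "urea": np.empty(n, dtype=float),
        "rr": np.empty(n, dtype=int),
        "sbp": np.empty(n, dtype=float),
        "dbp": np.empty(n, dtype=float),
    }
    pending = {c: list(np.flatnonzero(target_class == c)) for c in (0, 1, 2)}
    filled = 0
    while filled < n:
        m = max(4 * (n - filled), 1024)
        cand = _draw_covariates(rng, m)
        score = curb65_score_array(
            cand["age"], cand["confusion"], cand["urea"], cand["rr"], cand["sbp"], cand["dbp"]
        )
        cls = np.where(score <= 1, 0, np.where(score == 2, 1, 2))
        for c in (0, 1, 2):
            want = pending[c]
            if not want:
                continue
            hits = np.flatnonzero(cls == c)[: len(want)]
            take = want[: len(hits)]
            pending[c] = want[len(hits):]
            filled += len(take)
            idx = np.asarray(take, dtype=int)
            out["age"][idx] = cand["age"][hits]
            out["confusion"][idx] = cand["confusion"][hits]
            out["urea"][idx] = cand["urea"][hits]
            out["rr"][idx] = cand["rr"][hits]
            out["sbp"][idx] = cand["sbp"][hits]
            out["dbp"][idx] = cand["dbp"][hits]
    return out


def _sample_truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float, m: int
) -> np.ndarray:
    """Inverse-CDF sampling of log-normal(mu, sigma) truncated to (lo, hi]."""
    a = sps.norm.cdf((np.log(lo) - mu) / sigma)
    b = sps.norm.cdf((np.log(hi) - mu) / sigma) if np.isfinite(hi) else 1.0
    u = rng.uniform(a, b, m)
    x = np.exp(mu + sigma * sps.norm.ppf(u))
    return np.clip(x, lo + 1e-9 if lo > PROADM_DETECTION_LIMIT else lo, None)


def _calibrated_event_probs(
    logx: np.ndarray, slope: float, target_mean: float
) -> np.ndarray:
    """Per-patient probabilities expit(a + slope*logx) with mean pinned.

    Solves for the intercept a so the sample-average probability equals
    ``target_mean`` exactly, preserving the configured class rate whatever
    the realized biomarker draw.
    """
    if target_mean <= 0:
        return np.zeros_like(logx)
    if target_mean >= 1:
        return np.ones_like(logx)
    if slope == 0:
        return np.full_like(logx, target_mean)

    def gap(a):
        return expit(a + slope * logx).mean() - target_mean

    span = abs(slope) * (np.abs(logx).max() + 1)
    a = brentq(gap, np.log(target_mean / (1 - target_mean)) - span - 1,
               np.log(target_mean / (1 - target_mean)) + span + 1, xtol=1e-12)
    return expit(a + slope * logx)


def generate_cohort_frame(config: CohortConfig) -> pd.DataFrame:
    """Generate a cohort as a DataFrame in the cohort CSV schema."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    curb_cls = rng.choice(3, size=n, p=np.asarray(config.curb65_class_probs, dtype=float))
    cov = _sample_covariates_for_classes(rng, curb_cls)

    mat = np.asarray(config.proadm_cat_probs_given_curb65, dtype=float)
    u = rng.random(n)
    cum = mat.cumsum(axis=1)[curb_cls]
    proadm_cat = (u[:, None] > cum).sum(axis=1)

    proadm = np.empty(n)
    for j in range(3):
        idx = np.flatnonzero(proadm_cat == j)
        if idx.size:
            mu, sigma = config.proadm_lognormal_params_per_cat[j]
            lo, hi = _PROADM_BOUNDS[j]
            proadm[idx] = _sample_truncated_lognormal(rng, mu, sigma, lo, hi, idx.size)

    # CURB65-A class from the sampled grid cell
    risk = np.full(n, 3)
    risk[(curb_cls == 0) & (proadm_cat == 0)] = 1
    risk[((curb_cls == 0) & (proadm_cat == 1)) | ((curb_cls == 1) & (proadm_cat <= 1))] = 2

    adverse = np.zeros(n, dtype=bool)
    death = np.zeros(n, dtype=bool)
    logx = np.log(proadm)
    adv_p = np.asarray(config.adverse_probs_per_riskclass, dtype=float)
    mort_p = np.asarray(config.mortality_probs_per_riskclass, dtype=float)
    for k in (1, 2, 3):
        idx = np.flatnonzero(risk == k)
        if not idx.size:
            continue
        p_i = _calibrated_event_probs(
            logx[idx], config.within_class_proadm_slope, adv_p[k - 1]
        )
        adverse[idx] = rng.random(idx.size) < p_i
        # mortality as a sub-event of the composite: constant conditional
        # probability = configured ratio, so the class-marginal death rate
        # matches and deaths inherit the within-class biomarker gradient
        ratio = mort_p[k - 1] / adv_p[k - 1] if adv_p[k - 1] > 0 else 0.0
        hit = idx[adverse[idx]]
        death[hit] = rng.random(hit.size) < ratio

    diagnosis = rng.choice(
        [d.value for d in Diagnosis], size=n, p=np.asarray(config.diagnosis_probs, dtype=float)
    )

    # split the non-fatal composite into ICU vs disease-specific
    # complication; complications (empyema) occur only in pneumonia
    icu = np.zeros(n, dtype=bool)
    compl = np.zeros(n, dtype=bool)
    nonfatal = adverse & ~death
    is_cap = diagnosis == Diagnosis.CAP.value
    cap_nonfatal = np.flatnonzero(nonfatal & is_cap)
    compl[cap_nonfatal] = rng.random(cap_nonfatal.size) < 0.30
    icu[nonfatal & ~compl] = True
    icu_among_dead = np.flatnonzero(death)
    icu[icu_among_dead] |= rng.random(icu_among_dead.size) < 0.35

    out_rate = np.asarray(config.outpatient_rate_per_riskclass, dtype=float)
    outpatient = rng.random(n) < out_rate[risk - 1]

    return pd.DataFrame(
        {
            "age": cov["age"],
            "confusion": cov["confusion"].astype(int),
            "urea_mmol_l": cov["urea"],
            "resp_rate": cov["rr"],
            "sbp": cov["sbp"],
            "dbp": cov["dbp"],
            "proadm_nmol_l": proadm,
            "diagnosis": diagnosis,
            "death30": death.astype(int),
            "icu30": icu.astype(int),
            "complication30": compl.astype(int),
            "outpatient": outpatient.astype(int),
        }
    )


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate a cohort as a list of validated patient records."""
    from .io import frame_to_cohort

    return frame_to_cohort(generate_cohort_frame(config))


def describe_cohort(cohort) -> pd.DataFrame:
    """Baseline-characteristics summary in the usual Table-1 layout.

    Accepts a list of patient records or a cohort DataFrame. Returns a
    two-column frame (characteristic, value) with medians (IQR) for
    continuous variables and n (%) for categorical ones.
    """
    from .io import cohort_to_frame

    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    if df.empty:
        raise ValueError("cohort is empty")
    scored = score_cohort_frame(df)
    n = len(df)

    def med_iqr(col):
        q1, q2, q3 = np.percentile(df[col], [25, 50, 75])
        return f"{q2:.1f} ({q1:.1f}-{q3:.1f})"

    def n_pct(count):
        return f"{count} ({100 * count / n:.1f}%)"

    adverse = (df["death30"] | df["icu30"] | df["complication30"]).astype(bool)
    rows = [
        ("n", str(n)),
        ("Age, years, median (IQR)", med_iqr("age")),
        ("Confusion, n (%)", n_pct(int(df["confusion"].sum()))),
        ("Urea, mmol/L, median (IQR)", med_iqr("urea_mmol_l")),
        ("Respiratory rate, /min, median (IQR)", med_iqr("resp_rate")),
        ("Systolic BP, mmHg, median (IQR)", med_iqr("sbp")),
        ("Diastolic BP, mmHg, median (IQR)", med_iqr("dbp")),
        ("ProADM, nmol/L, median (IQR)", med_iqr("proadm_nmol_l")),
    ]
    for d in Diagnosis:
        rows.append((f"Diagnosis {d.value}, n (%)", n_pct(int((df["diagnosis"] == d.value).sum()))))
    for label, col, vals in (
        ("CURB65 class", "curb65_class", {0: "0-1", 1: "2", 2: "3-5"}),
        ("ProADM category", "proadm_cat", {0: "<=0.75", 1: "0.75-1.5", 2: ">1.5"}),
        ("CURB65-A class", "riskclass", {1: "I", 2: "II", 3: "III"}),
    ):
        for code, name in vals.items():
            rows.append((f"{label} {name}, n (%)", n_pct(int((scored[col] == code).sum()))))
    rows += [
        ("Adverse event (30 d), n (%)", n_pct(int(adverse.sum()))),
        ("Death (30 d), n (%)", n_pct(int(df["death30"].sum()))),
        ("Outpatient treatment, n (%)", n_pct(int(df["outpatient"].sum()))),
    ]
    return pd.DataFrame(rows, columns=["characteristic", "value"])
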