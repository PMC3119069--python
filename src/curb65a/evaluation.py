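"""The CURB65-A derivation pipeline.

Stratified risk tables with Wald intervals, AUC-based score comparison
(ordinal CURB65 / CURB65-A classes, continuous ProADM, and the joint
logistic model compared by the paired DeLong test), within-stratum decile
calibration, Cochran-Armitage trend tests across ProADM categories inside
each CURB65 class, and the triage-reallocation cross-tab that quantifies
how many actual in/outpatients the composite score would redirect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats_core as st
from .io import Subgroup, cohort_to_frame
from .scoring import Diagnosis, ScoreThresholds, score_cohort_frame

__all__ = [
    "RiskTable",
    "TriageCrosstab",
    "ModelComparison",
    "DecileCalibration",
    "prepare_frame",
    "filter_subgroup",
    "build_risk_table",
    "score_performance",
    "combined_model_comparison",
    "decile_calibration",
    "proadm_trend_within_curb65",
    "triage_reallocation",
    "write_report",
    "REPORT_SCHEMA",
]

_CURB65_LABELS = {0: "CURB65 0-1", 1: "CURB65 2", 2: "CURB65 3-5"}
_PROADM_LABELS = {0: "ProADM <=0.75 nmol/l", 1: "ProADM 0.75-1.5 nmol/l", 2: "ProADM >1.5 nmol/l"}
_RISK_LABELS = {1: "Risk class I", 2: "Risk class II", 3: "Risk class III"}


def prepare_frame(cohort, thresholds: ScoreThresholds | None = None) -> pd.DataFrame:
    """Normalize input (records or frame) to a scored cohort DataFrame."""
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    if df.empty:
        raise ValueError("cohort is empty")
    if "riskclass" not in df.columns:
        df = score_cohort_frame(df, thresholds or ScoreThresholds())
    df = df.copy()
    df["adverse"] = (
        df["death30"].astype(bool) | df["icu30"].astype(bool) | df["complication30"].astype(bool)
    ).astype(int)
    return df


def filter_subgroup(df: pd.DataFrame, subgroup: Subgroup | str) -> pd.DataFrame:
    """Restrict to CAP or non-CAP patients.

    Non-CAP means COPD exacerbation or bronchitis; patients with another
    final diagnosis belong to neither subgroup.
    """
    subgroup = Subgroup(subgroup) if not isinstance(subgroup, Subgroup) else subgroup
    if subgroup is Subgroup.ALL:
        return df
    if subgroup is Subgroup.CAP:
        return df[df["diagnosis"] == Diagnosis.CAP.value]
    return df[
        df["diagnosis"].isin(
            [Diagnosis.COPD_EXACERBATION.value, Diagnosis.BRONCHITIS.value]
        )
    ]


# ----------------------------------------------------------------- risk table


@dataclass
class RiskTableRow:
    stratum: str
    n: int
    adverse_ci: st.ProportionCI | None
    mortality_ci: st.ProportionCI | None


@dataclass
class RiskTable:
    """Stratified adverse-event and mortality rates with Wald intervals.

    One block per stratification (CURB65 classes, ProADM categories,
    CURB65-A classes) plus a Total row; empty strata keep n = 0 with the
    intervals flagged undefined (None).
    """

    rows: list[RiskTableRow]
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        def fmt(ci: st.ProportionCI | None):
            if ci is None:
                return (np.nan, np.nan, np.nan, np.nan)
            return (ci.events, round(ci.p_hat, 2), round(ci.lower, 2), round(ci.upper, 2))

        data = []
        for r in self.rows:
            a, m = fmt(r.adverse_ci), fmt(r.mortality_ci)
            data.append((r.stratum, r.n) + a + m)
        return pd.DataFrame(
            data,
            columns=[
                "stratum",
                "n",
                "adverse_events",
                "adverse_pct",
                "adverse_ci_lower",
                "adverse_ci_upper",
                "deaths",
                "mortality_pct",
                "mortality_ci_lower",
                "mortality_ci_upper",
            ],
        )


def _stratum_row(label: str, sub: pd.DataFrame) -> RiskTableRow:
    n = len(sub)
    if n == 0:
        return RiskTableRow(label, 0, None, None)
    return RiskTableRow(
        label,
        n,
        st.wald_ci(int(sub["adverse"].sum()), n),
        st.wald_ci(int(sub["death30"].sum()), n),
    )


def build_risk_table(cohort, subgroup: Subgroup | str = Subgroup.ALL) -> RiskTable:
    """Observed event rates by CURB65 class, ProADM category and CURB65-A class."""
    df = filter_subgroup(prepare_frame(cohort), subgroup)
    if df.empty:
        raise ValueError("no patients left after subgroup filtering")
    rows = []
    for col, labels in (
        ("curb65_class", _CURB65_LABELS),
        ("proadm_cat", _PROADM_LABELS),
        ("riskclass", _RISK_LABELS),
    ):
        for code, label in labels.items():
            rows.append(_stratum_row(label, df[df[col] == code]))
    rows.append(_stratum_row("Total", df))
    return RiskTable(rows=rows, n_total=len(df))


# ------------------------------------------------------------ discrimination


def score_performance(cohort, endpoint: str, subgroup: Subgroup | str = Subgroup.ALL) -> dict:
    """AUCs of the candidate predictors for one endpoint.

    Returns ``{"curb65_class": AucResult, "curb65a_class": AucResult,
    "proadm": AucResult}``; entries are None when the endpoint has no
    events (or no non-events) in the subgroup, making the AUC undefined.
    """
    df = filter_subgroup(prepare_frame(cohort), subgroup)
    y = _endpoint(df, endpoint)
    out: dict[str, st.AucResult | None] = {}
    if y.sum() == 0 or y.sum() == len(y):
        return {"curb65_class": None, "curb65a_class": None, "proadm": None}
    for key, col, levels in (
        ("curb65_class", "curb65_class", (0, 1, 2)),
        ("curb65a_class", "riskclass", (1, 2, 3)),
    ):
        cases = [int(((df[col] == lv) & (y == 1)).sum()) for lv in levels]
        controls = [int(((df[col] == lv) & (y == 0)).sum()) for lv in levels]
        out[key] = st.ordinal_auc(cases, controls)
    out["proadm"] = st.continuous_auc(
        df.loc[y == 1, "proadm_nmol_l"], df.loc[y == 0, "proadm_nmol_l"]
    )
    return out


def _endpoint(df: pd.DataFrame, endpoint: str) -> np.ndarray:
    if endpoint == "adverse":
        return df["adverse"].to_numpy()
    if endpoint == "mortality":
        return df["death30"].to_numpy()
    raise ValueError(f"endpoint must be 'adverse' or 'mortality', got {endpoint!r}")


@dataclass(frozen=True)
class ModelComparison:
    """CURB65-only vs CURB65 + log-ProADM logistic models, paired DeLong."""

    auc_curb65: st.AucResult
    auc_joint: st.AucResult
    p_value: float

    def to_dict(self) -> dict:
        return {
            "auc_curb65": self.auc_curb65.to_dict(),
            "auc_joint": self.auc_joint.to_dict(),
            "p_value": self.p_value,
        }


def combined_model_comparison(
    cohort, endpoint: str, subgroup: Subgroup | str = Subgroup.ALL
) -> ModelComparison:
    """Does adding log-ProADM to the CURB65 score improve discrimination?

    Both models are fit and evaluated in-sample (apparent AUC); the ROC
    curves are compared with the paired DeLong test.
    """
    df = filter_subgroup(prepare_frame(cohort), subgroup)
    y = _endpoint(df, endpoint)
    if y.sum() < 50:
        raise ValueError(f"need >= 50 events for model comparison, got {int(y.sum())}")
    x_curb = df["curb65"].to_numpy(dtype=float)[:, None]
    x_joint = np.column_stack([x_curb[:, 0], np.log(df["proadm_nmol_l"].to_numpy())])
    p_curb = st.logistic_fit(x_curb, y).predict(x_curb)
    p_joint = st.logistic_fit(x_joint, y).predict(x_joint)
    cmp = st.compare_roc_delong(p_curb, p_joint, y)
    return ModelComparison(auc_curb65=cmp.auc_a, auc_joint=cmp.auc_b, p_value=cmp.p_value)


# ----------------------------------------------------------------- calibration


@dataclass
class DecileCalibration:
    """Within-CURB65-stratum ProADM calibration display plus HL test.

    ``bins`` holds one row per ProADM decile (range, n, observed events,
    model-expected events); the Hosmer-Lemeshow statistic is computed on
    deciles of predicted probability.
    """

    stratum: int
    endpoint: str
    bins: pd.DataFrame
    hl: st.CalibrationResult
    slope: float
    slope_ci: tuple[float, float]


def decile_calibration(cohort, curb65_stratum: int, endpoint: str) -> DecileCalibration:
    """Fit logit(event) ~ log ProADM inside one CURB65 class; check calibration."""
    df = prepare_frame(cohort)
    sub = df[df["curb65_class"] == int(curb65_stratum)]
    if len(sub) < 100:
        raise ValueError(
            f"CURB65 stratum {curb65_stratum} has n = {len(sub)} < 100; "
            "calibration by deciles is not meaningful"
        )
    y = _endpoint(sub, endpoint)
    logx = np.log(sub["proadm_nmol_l"].to_numpy())
    fit = st.logistic_fit(logx[:, None], y)
    pred = fit.predict(logx[:, None])
    se_slope = float(np.sqrt(fit.cov[1, 1]))
    slope = float(fit.coefficients[1])

    order = np.argsort(sub["proadm_nmol_l"].to_numpy(), kind="stable")
    rows = []
    for g in np.array_split(order, 10):
        x_g = sub["proadm_nmol_l"].to_numpy()[g]
        rows.append(
            {
                "proadm_min": float(x_g.min()),
                "proadm_max": float(x_g.max()),
                "n": len(g),
                "observed": int(y[g].sum()),
                "expected": float(pred[g].sum()),
            }
        )
    return DecileCalibration(
        stratum=int(curb65_stratum),
        endpoint=endpoint,
        bins=pd.DataFrame(rows),
        hl=st.hosmer_lemeshow(pred, y),
        slope=slope,
        slope_ci=(slope - 1.959964 * se_slope, slope + 1.959964 * se_slope),
    )


# ----------------------------------------------------------------------- trend


def proadm_trend_within_curb65(cohort, curb65_stratum: int, endpoint: str) -> st.TrendResult:
    """Cochran-Armitage trend across ProADM categories within one CURB65 class."""
    df = prepare_frame(cohort)
    sub = df[df["curb65_class"] == int(curb65_stratum)]
    if sub.empty:
        raise ValueError(f"CURB65 stratum {curb65_stratum} is empty")
    y = _endpoint(sub, endpoint)
    events, totals = [], []
    for cat in (0, 1, 2):
        mask = sub["proadm_cat"] == cat
        if mask.sum() == 0:
            warnings.warn(
                f"ProADM category {cat} absent in stratum {curb65_stratum}; "
                "trend computed on remaining categories",
                RuntimeWarning,
            )
            continue
        events.append(int(y[mask].sum()))
        totals.append(int(mask.sum()))
    return st.trend_test(events, totals)


# ---------------------------------------------------------------------- triage


@dataclass
class TriageCrosstab:
    """Actual site of care vs CURB65-A recommendation.

    ``counts`` is a 2x3 table (rows: outpatient, inpatient; columns:
    recommended outpatient / short hospitalization / inpatient);
    ``row_pct`` the corresponding row percentages. The headline fractions
    summarize reallocation potential among actually hospitalized patients.
    """

    counts: pd.DataFrame
    row_pct: pd.DataFrame
    inpatients_to_outpatient_pct: float
    inpatients_to_short_stay_pct: float

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(),
            "row_pct": self.row_pct.round(1).to_dict(),
            "inpatients_to_outpatient_pct": self.inpatients_to_outpatient_pct,
            "inpatients_to_short_stay_pct": self.inpatients_to_short_stay_pct,
        }


_REC_COLUMNS = ["outpatient", "short_hospitalization", "inpatient"]


def triage_reallocation(cohort) -> TriageCrosstab:
    """Cross-tabulate actual site of care against the CURB65-A recommendation."""
    df = prepare_frame(cohort)
    actual = np.where(df["outpatient"].astype(bool), "outpatient", "inpatient")
    counts = pd.DataFrame(0, index=["outpatient", "inpatient"], columns=_REC_COLUMNS)
    tab = pd.crosstab(actual, df["recommendation"])
    for r in counts.index:
        for c in counts.columns:
            if r in tab.index and c in tab.columns:
                counts.loc[r, c] = int(tab.loc[r, c])
    row_tot = counts.sum(axis=1)
    row_pct = counts.div(row_tot.replace(0, np.nan), axis=0) * 100
    n_in = int(row_tot["inpatient"])
    return TriageCrosstab(
        counts=counts,
        row_pct=row_pct,
        inpatients_to_outpatient_pct=(
            100 * counts.loc["inpatient", "outpatient"] / n_in if n_in else float("nan")
        ),
        inpatients_to_short_stay_pct=(
            100 * counts.loc["inpatient", "short_hospitalization"] / n_in if n_in else float("nan")
        ),
    )


# ---------------------------------------------------------------------- report

REPORT_SCHEMA = {
    "risk_table.tsv": {
        "stratum": "row label: CURB65 class / ProADM category / CURB65-A class / Total",
        "n": "patients in stratum",
        "adverse_events": "observed 30-day adverse events (death, ICU, complication)",
        "adverse_pct": "adverse-event rate, % (2 dp)",
        "adverse_ci_lower": "Wald 95% lower bound, % (may be negative)",
        "adverse_ci_upper": "Wald 95% upper bound, %",
        "deaths": "observed 30-day deaths",
        "mortality_pct": "mortality rate, % (2 dp)",
        "mortality_ci_lower": "Wald 95% lower bound, %",
        "mortality_ci_upper": "Wald 95% upper bound, %",
    },
    "performance.json": {
        "<endpoint>.<predictor>": "AUC with DeLong se and 95% CI; predictors: "
        "curb65_class (ordinal 0-1/2/3-5), curb65a_class (ordinal I/II/III), "
        "proadm (continuous nmol/L)",
        "<endpoint>.combined_model": "CURB65-only vs CURB65+log(ProADM) apparent "
        "AUCs and paired DeLong p-value",
        "<endpoint>.trend_by_curb65_class": "Cochran-Armitage z and two-sided p "
        "across ProADM categories within each CURB65 class",
    },
    "triage_crosstab.tsv": {
        "actual": "observed site of care (outpatient = discharged <= 1 day)",
        "recommended_*": "counts by CURB65-A recommendation",
        "pct_*": "row percentages (1 dp)",
    },
    "calibration_<stratum>_<endpoint>.tsv": {
        "proadm_min/proadm_max": "ProADM decile range, nmol/L",
        "n": "patients in decile",
        "observed": "observed events",
        "expected": "events expected under the within-stratum log-ProADM logistic model",
    },
}


def write_report(
    cohort,
    output_dir,
    subgroup: Subgroup | str = Subgroup.ALL,
    min_events_for_models: int = 50,
) -> dict:
    """Run the full evaluation and write the report bundle.

    Emits risk_table.tsv, performance.json, triage_crosstab.tsv, decile
    calibration TSVs per feasible (CURB65 class, endpoint) pair, and
    schema.json documenting every column. Returns the performance dict.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = filter_subgroup(prepare_frame(cohort), subgroup)
    if df.empty:
        raise ValueError("no patients in requested subgroup")

    build_risk_table(df).to_frame().to_csv(out / "risk_table.tsv", sep="\t", index=False)

    performance: dict = {}
    for endpoint in ("adverse", "mortality"):
        block: dict = {}
        aucs = score_performance(df, endpoint)
        for k, v in aucs.items():
            block[k] = None if v is None else v.to_dict()
        try:
            block["combined_model"] = combined_model_comparison(df, endpoint).to_dict()
        except ValueError as exc:
            block["combined_model"] = {"error": str(exc)}
        trend = {}
        for stratum in (0, 1, 2):
            try:
                trend[_CURB65_LABELS[stratum]] = proadm_trend_within_curb65(
                    df, stratum, endpoint
                ).to_dict()
            except ValueError as exc:
                trend[_CURB65_LABELS[stratum]] = {"error": str(exc)}
        block["trend_by_curb65_class"] = trend
        performance[endpoint] = block

        for stratum in (0, 1, 2):
            try:
                cal = decile_calibration(df, stratum, endpoint)
            except (ValueError, st.SeparationError):
                continue
            cal.bins.to_csv(
                out / f"calibration_curb65class{stratum}_{endpoint}.tsv",
                sep="\t",
                index=False,
            )

    tri = triage_reallocation(df)
    tri_tab = tri.counts.copy()
    tri_tab.columns = [f"recommended_{c}" for c in tri_tab.columns]
    for c in _REC_COLUMNS:
        tri_tab[f"pct_{c}"] = tri.row_pct[c].round(1)
    tri_tab.insert(0, "actual", tri_tab.index)
    tri_tab.to_csv(out / "triage_crosstab.tsv", sep="\t", index=False)

    with open(out / "performance.json", "w", encoding="utf-8") as fh:
        json.dump(performance, fh, indent=2)
    with open(out / "schema.json", "w", encoding="utf-8") as fh:
        json.dump(REPORT_SCHEMA, fh, indent=2)
    return performance
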