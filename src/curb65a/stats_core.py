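"""Statistical primitives for risk-score derivation.

Self-contained building blocks: Wald proportion intervals, ties-corrected
Mann-Whitney AUC with DeLong standard errors and the paired DeLong test,
logistic regression (maximum likelihood via IRLS, backed by statsmodels),
the Hosmer-Lemeshow calibration test, the Cochran-Armitage trend test, and
a spline-logistic smoothed risk curve.

All functions are pure: inputs in, result dataclasses out. Results carry a
``to_dict`` for flat JSON reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats as sps
from scipy.special import expit, logit
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "ProportionCI",
    "AucResult",
    "LogisticFit",
    "CalibrationResult",
    "TrendResult",
    "RocComparison",
    "SeparationError",
    "SingularityError",
    "wald_ci",
    "count_from_rate",
    "ordinal_auc",
    "continuous_auc",
    "logistic_fit",
    "compare_roc_delong",
    "hosmer_lemeshow",
    "trend_test",
    "smoothed_risk_curve",
]


class SeparationError(RuntimeError):
    """Logistic fit failed to converge because of (quasi-)complete separation."""


class SingularityError(ValueError):
    """Design matrix is rank deficient (collinear columns)."""


# ---------------------------------------------------------------- proportions


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with a normal-approximation (Wald) interval.

    All three summary values are on the percent scale; bounds are not
    truncated at 0 or 100, so small event counts can yield a negative
    lower bound — exactly how such intervals appear in clinical tables.
    """

    events: int
    n: int
    p_hat: float  # %
    lower: float  # %
    upper: float  # %
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "events": self.events,
            "n": self.n,
            "p_hat_pct": self.p_hat,
            "ci_lower_pct": self.lower,
            "ci_upper_pct": self.upper,
            "level": self.level,
        }


def wald_ci(events: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wald interval p-hat +/- z*sqrt(p(1-p)/n), reported in percent."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= events <= n:
        raise ValueError(f"events must be in 0..n, got {events}/{n}")
    p = events / n
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return ProportionCI(
        events=int(events),
        n=int(n),
        p_hat=100 * p,
        lower=100 * (p - half),
        upper=100 * (p + half),
        level=level,
    )


def count_from_rate(n: int, percent: float) -> int:
    """Recover an integer event count from a printed percentage.

    Rounds n*percent/100 to the nearest integer, halves away from zero —
    the convention needed to reconstruct counts from published rate tables.
    """
    if n < 0 or not 0 <= percent <= 100:
        raise ValueError("need n >= 0 and 0 <= percent <= 100")
    return int(np.floor(n * percent / 100 + 0.5))


# ------------------------------------------------------------------------ AUC


@dataclass(frozen=True)
class AucResult:
    """Ties-corrected Mann-Whitney AUC with DeLong standard error."""

    auc: float
    se: float
    ci_lower: float
    ci_upper: float
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


def _placements(cases: np.ndarray, controls: np.ndarray):
    """DeLong structural components via midranks.

    Returns (auc, V10, V01): per-case and per-control placement values.
    """
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    r_all = sps.rankdata(combined)  # midranks over the pooled sample
    r_cases = sps.rankdata(cases)
    r_controls = sps.rankdata(controls)
    # placement of case i among controls: (pooled rank - within rank)/n
    v10 = (r_all[:m] - r_cases) / n
    v01 = 1.0 - (r_all[m:] - r_controls) / m
    auc = v10.mean()
    return auc, v10, v01


def _delong_se(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def continuous_auc(
    case_values: np.ndarray, control_values: np.ndarray, level: float = 0.95
) -> AucResult:
    """AUC of a continuous marker: P(case > control) + 0.5 P(tie)."""
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control")
    auc, v10, v01 = _placements(cases, controls)
    se = _delong_se(v10, v01)
    z = sps.norm.ppf(0.5 + level / 2)
    return AucResult(
        auc=float(auc),
        se=se,
        ci_lower=float(max(0.0, auc - z * se)),
        ci_upper=float(min(1.0, auc + z * se)),
        n_cases=len(cases),
        n_controls=len(controls),
    )


def ordinal_auc(
    case_counts, control_counts, level: float = 0.95
) -> AucResult:
    """AUC of an ordinal predictor given per-level case/control counts.

    Identical to ``continuous_auc`` on the expanded level values; levels
    are scored 0,1,2,... in their given order.
    """
    cc = np.asarray(case_counts, dtype=int)
    kc = np.asarray(control_counts, dtype=int)
    if cc.shape != kc.shape or cc.ndim != 1 or len(cc) < 2:
        raise ValueError("case and control counts must share >= 2 ordered levels")
    if cc.sum() < 1 or kc.sum() < 1:
        raise ValueError("need at least one case and one control")
    levels = np.arange(len(cc), dtype=float)
    return continuous_auc(np.repeat(levels, cc), np.repeat(levels, kc), level=level)


# ------------------------------------------------------------------- logistic


@dataclass
class LogisticFit:
    """A converged maximum-likelihood logistic regression.

    ``coefficients`` holds the intercept followed by slopes, on the
    log-odds scale. ``predict`` evaluates fitted probabilities for a new
    slope-covariate matrix (the intercept column is added internally).
    """

    coefficients: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    cov: np.ndarray = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        design = np.column_stack([np.ones(len(X)), X])
        return expit(design @ self.coefficients)

    def to_dict(self) -> dict:
        return {
            "coefficients": list(map(float, self.coefficients)),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik": self.loglik,
        }


_MAX_COEF = 1e4  # coefficient-norm guard: beyond this we call it separation


def logistic_fit(
    design: np.ndarray,
    outcome: np.ndarray,
    add_intercept: bool = True,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> LogisticFit:
    """Fit a binary-outcome logistic regression by IRLS.

    ``design`` holds the slope covariates (an intercept is prepended when
    ``add_intercept``). Raises on a constant outcome, a rank-deficient
    design, or complete separation.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(y):
        raise ValueError("design and outcome lengths differ")
    if y.min() == y.max():
        raise ValueError("outcome is constant; logistic model is undefined")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularityError("design matrix is rank deficient (collinear columns)")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=tol, maxiter=maxiter)
    separated = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    if separated or np.abs(res.params).max() > _MAX_COEF:
        raise SeparationError(
            "logistic fit did not converge: (quasi-)complete separation detected"
        )
    return LogisticFit(
        coefficients=np.asarray(res.params, dtype=float),
        converged=bool(res.converged),
        n_iter=int(res.fit_history["iteration"]),
        loglik=float(res.llf),
        cov=np.asarray(res.cov_params(), dtype=float),
    )


# --------------------------------------------------------------- paired DeLong


@dataclass(frozen=True)
class RocComparison:
    """Paired DeLong comparison of two correlated ROC curves."""

    auc_a: AucResult
    auc_b: AucResult
    p_value: float

    def to_dict(self) -> dict:
        return {
            "auc_a": self.auc_a.to_dict(),
            "auc_b": self.auc_b.to_dict(),
            "p_value": self.p_value,
        }


def compare_roc_delong(
    fit_a_scores: np.ndarray, fit_b_scores: np.ndarray, outcome: np.ndarray
) -> RocComparison:
    """Two-sided DeLong test for the AUC difference of two paired markers.

    Both score vectors must be aligned to the same subjects; ``outcome``
    flags cases. Rank-identical markers give p = 1 exactly.
    """
    a = np.asarray(fit_a_scores, dtype=float)
    b = np.asarray(fit_b_scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("score vectors and outcome must have equal length")

    auc_a, v10_a, v01_a = _placements(a[y], a[~y])
    auc_b, v10_b, v01_b = _placements(b[y], b[~y])
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("need at least one case and one control")

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if np.isclose(diff, 0.0) else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * sps.norm.sf(abs(z)))

    z_ci = sps.norm.ppf(0.975)

    def _res(auc, v10, v01):
        se = _delong_se(v10, v01)
        return AucResult(
            auc=float(auc),
            se=se,
            ci_lower=float(max(0.0, auc - z_ci * se)),
            ci_upper=float(min(1.0, auc + z_ci * se)),
            n_cases=m,
            n_controls=n,
        )

    return RocComparison(_res(auc_a, v10_a, v01_a), _res(auc_b, v10_b, v01_b), p)


# ---------------------------------------------------------------- calibration


@dataclass
class CalibrationResult:
    """Hosmer-Lemeshow style observed/expected comparison over risk bins."""

    bins: list  # (bin_range, n, observed_events, expected_events)
    chi2: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "bins": [
                {
                    "range": [float(lo), float(hi)],
                    "n": int(n),
                    "observed": float(o),
                    "expected": float(e),
                }
                for (lo, hi), n, o, e in self.bins
            ],
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }


def hosmer_lemeshow(
    predicted: np.ndarray, observed: np.ndarray, n_groups: int = 10
) -> CalibrationResult:
    """Hosmer-Lemeshow goodness-of-fit over deciles of predicted risk.

    Groups subjects into ``n_groups`` near-equal bins of predicted
    probability (ties kept in stable input order), then compares observed
    and expected event counts with chi2 = sum (O-E)^2 / (E(1-E/n_g)) on
    ``n_groups - 2`` degrees of freedom. Bins whose expected count is zero
    are merged into their neighbour with a warning and the df reduced.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if len(p) != len(y):
        raise ValueError("predicted and observed lengths differ")
    if not ((p > 0) & (p < 1)).all():
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    if len(p) < n_groups:
        raise ValueError("need at least n_groups observations")

    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_groups)
    rows = []
    for g in groups:
        rows.append(
            [float(p[g].min()), float(p[g].max()), len(g), float(y[g].sum()), float(p[g].sum())]
        )

    # merge empty-expectation bins forward (or backward for the last bin)
    merged = []
    for row in rows:
        if merged and merged[-1][4] == 0.0:
            prev = merged.pop()
            row = [prev[0], row[1], prev[2] + row[2], prev[3] + row[3], prev[4] + row[4]]
            warnings.warn("merged a zero-expected-count bin", RuntimeWarning)
        merged.append(row)
    if len(merged) > 1 and merged[-1][4] == 0.0:
        last = merged.pop()
        prev = merged.pop()
        merged.append(
            [prev[0], last[1], prev[2] + last[2], prev[3] + last[3], prev[4] + last[4]]
        )
        warnings.warn("merged a zero-expected-count bin", RuntimeWarning)

    chi2 = 0.0
    bins = []
    for lo, hi, n_g, obs, exp in merged:
        denom = exp * (1 - exp / n_g)
        if denom > 0:
            chi2 += (obs - exp) ** 2 / denom
        bins.append(((lo, hi), n_g, obs, exp))
    df = max(len(merged) - 2, 1)
    return CalibrationResult(
        bins=bins, chi2=float(chi2), df=df, p_value=float(sps.chi2.sf(chi2, df))
    )


# ---------------------------------------------------------------------- trend


@dataclass(frozen=True)
class TrendResult:
    """Cochran-Armitage trend test across ordered exposure levels."""

    z: float
    p_value: float
    note: str = ""

    def to_dict(self) -> dict:
        return {"z": self.z, "p_value": self.p_value, "note": self.note}


def trend_test(events_by_level, n_by_level) -> TrendResult:
    """Cochran-Armitage test with equally spaced scores; two-sided p.

    Equivalent to the 1-df score test of a logistic regression on the
    level scores. Zero events everywhere is flagged and returns p = 1.
    """
    e = np.asarray(events_by_level, dtype=float)
    n = np.asarray(n_by_level, dtype=float)
    if e.shape != n.shape or e.ndim != 1 or len(e) < 2:
        raise ValueError("need aligned event/total counts for >= 2 levels")
    if (e > n).any() or (e < 0).any() or (n <= 0).any():
        raise ValueError("need 0 <= events <= n and n > 0 per level")
    total_e, total_n = e.sum(), n.sum()
    if total_e == 0:
        return TrendResult(z=0.0, p_value=1.0, note="no events: trend undetectable")
    if total_e == total_n:
        return TrendResult(z=0.0, p_value=1.0, note="all events: trend undetectable")
    s = np.arange(1, len(e) + 1, dtype=float)
    p_bar = total_e / total_n
    u = float(np.sum(e * s) - p_bar * np.sum(n * s))  # score statistic
    v = float(p_bar * (1 - p_bar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / total_n))
    if v <= 0:
        return TrendResult(z=0.0, p_value=1.0, note="degenerate score variance")
    z = u / np.sqrt(v)
    return TrendResult(z=float(z), p_value=float(2 * sps.norm.sf(abs(z))))


# ----------------------------------------------------------- smoothed curves


def smoothed_risk_curve(
    x: np.ndarray,
    y: np.ndarray,
    df: int = 4,
    grid_size: int = 100,
    level: float = 0.95,
) -> pd.DataFrame:
    """Smoothed event risk as a function of a biomarker.

    Fits a logistic regression on a natural-cubic-spline basis of ``x``
    with the requested degrees of freedom, and evaluates it on a uniform
    grid spanning the 1st-99th percentile of ``x`` with pointwise Wald
    confidence bands on the probability scale (delta method on the linear
    predictor). Returns a DataFrame with columns x, risk, lower, upper.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 50:
        raise ValueError("need at least 50 observations to smooth")
    if df < 2:
        raise ValueError("df must be >= 2")
    if x.min() == x.max():
        raise ValueError("x is constant; no curve can be fit")

    # the natural-spline basis spans the constant function, so it is fit
    # without a separate intercept: df columns = df model degrees of freedom
    basis_info = dmatrix(f"cr(x, df={df}) - 1", {"x": x})
    fit = logistic_fit(np.asarray(basis_info), y, add_intercept=False)

    lo, hi = np.percentile(x, [1, 99])
    grid = np.linspace(lo, hi, grid_size)
    design = np.asarray(dmatrix(basis_info.design_info, {"x": grid}))
    eta = design @ fit.coefficients
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", design, fit.cov, design))
    z = sps.norm.ppf(0.5 + level / 2)
    return pd.DataFrame(
        {
            "x": grid,
            "risk": expit(eta),
            "lower": expit(eta - z * se_eta),
            "upper": expit(eta + z * se_eta),
        }
    )
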