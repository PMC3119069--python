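"""Statistical primitives: Wald CIs, AUCs, logistic fits, HL, trend tests."""

import numpy as np
import pytest
from scipy.special import expit, logit

from curb65a import stats_core as st


# ----------------------------------------------------------- Wald proportions


class TestWaldCI:
    def test_total_row_values(self):
        r = st.wald_ci(170, 1359)
        assert (round(r.p_hat, 2), round(r.lower, 2), round(r.upper, 2)) == (
            12.51,
            10.75,
            14.27,
        )

    def test_degenerate_at_zero_events(self):
        r = st.wald_ci(0, 100)
        assert r.p_hat == r.lower == r.upper == 0.0

    def test_negative_lower_bound_is_kept(self):
        r = st.wald_ci(3, 353)
        assert round(r.lower, 2) == -0.11
        assert r.lower < 0 < r.p_hat

    def test_rejects_empty_sample(self):
        with pytest.raises(ValueError):
            st.wald_ci(0, 0)

    def test_width_scales_as_inverse_sqrt_n(self):
        a = st.wald_ci(30, 200)
        b = st.wald_ci(120, 800)
        assert (a.upper - a.lower) / (b.upper - b.lower) == pytest.approx(2, abs=1e-9)


@pytest.mark.parametrize(
    "n, pct, expected",
    [(659, 0.76, 5), (1359, 12.51, 170), (100, 0, 0), (434, 8.06, 35), (306, 0.65, 2)],
)
def test_count_from_rate(n, pct, expected):
    assert st.count_from_rate(n, pct) == expected


# ------------------------------------------------------------------------ AUC


class TestAuc:
    def test_ordinal_identical_distributions(self):
        assert st.ordinal_auc([10, 10], [10, 10]).auc == pytest.approx(0.5)

    def test_ordinal_perfect_separation(self):
        assert st.ordinal_auc([0, 0, 5], [5, 0, 0]).auc == pytest.approx(1.0)

    def test_ordinal_mortality_by_curb65_class(self):
        r = st.ordinal_auc([5, 35, 27], [654, 399, 239])
        assert round(r.auc, 2) == 0.73

    def test_continuous_trivial(self):
        assert st.continuous_auc([2, 3], [0, 1]).auc == 1.0
        assert st.continuous_auc([1], [1]).auc == 0.5

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError):
            st.continuous_auc([], [1.0])
        with pytest.raises(ValueError):
            st.ordinal_auc([0, 0], [3, 3])

    def test_continuous_equals_ordinal_on_discrete_values(self):
        cases, controls = [3, 1, 4], [7, 2, 6]
        levels = np.arange(3, dtype=float)
        a = st.ordinal_auc(cases, controls)
        b = st.continuous_auc(np.repeat(levels, cases), np.repeat(levels, controls))
        assert a.auc == pytest.approx(b.auc, abs=0)
        assert a.se == pytest.approx(b.se, abs=0)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(7)
        x = rng.normal(1, 1, 80)
        y = rng.normal(0, 1, 120)
        a, b = st.continuous_auc(x, y), st.continuous_auc(y, x)
        assert a.auc == pytest.approx(1 - b.auc, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_matches_brute_force_pair_count(self):
        rng = np.random.default_rng(12)
        cases = np.round(rng.normal(1, 1, 60), 1)  # rounding forces ties
        controls = np.round(rng.normal(0.5, 1, 90), 1)
        gt = (cases[:, None] > controls[None, :]).sum()
        ties = (cases[:, None] == controls[None, :]).sum()
        expected = (gt + 0.5 * ties) / (len(cases) * len(controls))
        assert st.continuous_auc(cases, controls).auc == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------------------- logistic


class TestLogisticFit:
    def test_two_by_two_matches_odds_ratio_closed_form(self):
        # exposed: 30/100 events; unexposed: 10/100 events
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        fit = st.logistic_fit(x[:, None], y)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(10 / 90), abs=1e-8)
        assert fit.coefficients[1] == pytest.approx(
            np.log((30 / 70) / (10 / 90)), abs=1e-8
        )

    def test_intercept_only_returns_logit_of_mean(self):
        y = np.r_[np.ones(13), np.zeros(37)]
        fit = st.logistic_fit(np.empty((50, 0)), y)
        assert fit.coefficients[0] == pytest.approx(logit(0.26), abs=1e-10)

    def test_constant_outcome_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            st.logistic_fit(np.arange(10.0)[:, None], np.zeros(10))

    def test_collinear_design_is_a_singularity_error(self):
        x = np.arange(20.0)
        y = (x > 10).astype(float)
        with pytest.raises(st.SingularityError):
            st.logistic_fit(np.column_stack([x, 2 * x]), y)

    def test_complete_separation_is_detected(self):
        x = np.arange(20.0)
        y = (x >= 10).astype(float)
        with pytest.raises(st.SeparationError):
            st.logistic_fit(x[:, None], y)

    def test_score_equations_hold_at_convergence(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = (rng.random(500) < expit(-0.5 + 0.8 * x)).astype(float)
        fit = st.logistic_fit(x[:, None], y)
        resid = y - fit.predict(x[:, None])
        assert abs(resid.sum()) < 1e-6
        assert abs((resid * x).sum()) < 1e-6


# --------------------------------------------------------------------- DeLong


class TestDelongComparison:
    def test_identical_scores(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=200)
        y = rng.random(200) < 0.3
        r = st.compare_roc_delong(s, s, y)
        assert r.p_value == 1.0
        assert r.auc_a.auc == r.auc_b.auc

    def test_rank_preserving_shift_gives_p_one(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=200)
        y = rng.random(200) < 0.3
        r = st.compare_roc_delong(s, s + 5.0, y)
        assert r.p_value == 1.0

    def test_informative_added_covariate_wins(self):
        rng = np.random.default_rng(9)
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = rng.random(n) < expit(-1 + 0.7 * x1 + 0.9 * x2)
        r = st.compare_roc_delong(x1, 0.7 * x1 + 0.9 * x2, y)
        assert r.auc_b.auc > r.auc_a.auc
        assert r.p_value < 0.05

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            st.compare_roc_delong([1, 2], [1, 2, 3], [0, 1, 1])


# ------------------------------------------------------------ Hosmer-Lemeshow


class TestHosmerLemeshow:
    def test_perfectly_calibrated_constant_risk(self):
        p = np.full(100, 0.5)
        y = np.tile([1, 0], 50)  # exactly half events in every stable decile
        r = st.hosmer_lemeshow(p, y)
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)
        assert r.df == 8

    def test_gross_miscalibration_rejected(self):
        r = st.hosmer_lemeshow(np.full(100, 0.9), np.zeros(100))
        assert r.p_value < 0.001

    def test_bin_bookkeeping(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 205)
        y = (rng.random(205) < p).astype(float)
        r = st.hosmer_lemeshow(p, y)
        assert sum(b[1] for b in r.bins) == 205
        assert r.df == len(r.bins) - 2

    def test_rejects_probabilities_outside_open_interval(self):
        with pytest.raises(ValueError):
            st.hosmer_lemeshow(np.r_[np.full(19, 0.5), 1.0], np.zeros(20))


# ---------------------------------------------------------------------- trend


class TestTrendTest:
    def test_flat_rates_no_trend(self):
        r = st.trend_test([10, 10, 10], [100, 100, 100])
        assert r.z == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_strong_trend(self):
        assert st.trend_test([1, 10, 30], [100, 100, 100]).p_value < 0.001

    def test_no_events_flagged(self):
        r = st.trend_test([0, 0, 0], [50, 50, 50])
        assert r.p_value == 1.0
        assert "no events" in r.note

    def test_two_levels_equals_two_proportion_z_test(self):
        e, n = np.array([12.0, 30.0]), np.array([100.0, 120.0])
        r = st.trend_test(e, n)
        p_pool = e.sum() / n.sum()
        z_expected = (e[1] / n[1] - e[0] / n[0]) / np.sqrt(
            p_pool * (1 - p_pool) * (1 / n[0] + 1 / n[1])
        )
        assert abs(r.z) == pytest.approx(abs(z_expected), abs=1e-10)


# ------------------------------------------------------------ smoothed curve


class TestSmoothedRiskCurve:
    def test_flat_when_outcome_ignores_marker(self):
        rng = np.random.default_rng(21)
        x = rng.uniform(0.1, 4.0, 5000)
        y = (rng.random(5000) < 0.2).astype(float)
        curve = st.smoothed_risk_curve(x, y)
        assert len(curve) == 100
        assert np.abs(curve["risk"] - y.mean()).max() < 0.05

    def test_recovers_logistic_truth_within_band(self):
        rng = np.random.default_rng(22)
        x = rng.normal(0, 1, 5000)
        truth = expit(-1.5 + 1.0 * x)
        y = (rng.random(5000) < truth).astype(float)
        curve = st.smoothed_risk_curve(x, y)
        true_on_grid = expit(-1.5 + 1.0 * curve["x"])
        inside = (true_on_grid >= curve["lower"]) & (true_on_grid <= curve["upper"])
        assert inside.mean() >= 0.90

    def test_monotone_generating_model_yields_monotone_center(self):
        rng = np.random.default_rng(23)
        x = rng.lognormal(0, 0.6, 5000)
        y = (rng.random(5000) < expit(-2 + 1.2 * np.log(x))).astype(float)
        curve = st.smoothed_risk_curve(x, y)
        central = curve["risk"].to_numpy()[10:90]
        assert (np.diff(central) >= -1e-9).all()

    def test_constant_marker_is_an_error(self):
        with pytest.raises(ValueError):
            st.smoothed_risk_curve(np.ones(100), np.tile([0, 1], 50))

    def test_needs_enough_observations(self):
        with pytest.raises(ValueError):
            st.smoothed_risk_curve(np.arange(30.0), np.tile([0, 1], 15))
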