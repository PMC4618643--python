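"""NCA engine: trapezoid rules, lambda-z selection, gating, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from crosspk import (
    DoseEvent,
    PkParameters,
    accumulation_and_linearity,
    auc_lin_up_log_down,
    compute_cmax_tmax,
    extrapolate_auc,
    fit_lambda_z,
    geometric_summary,
    infusion_concentration,
    nca_profile,
)
from crosspk.designs import DAY1_SCHEDULE
from crosspk.nca import DataError, NcaResult, auc_between, prepare_profile


class TestCmaxTmax:
    def test_singleton(self):
        assert compute_cmax_tmax([1.0], [5.0]) == (5.0, 1.0)

    def test_tie_broken_to_earliest_time(self):
        times = [0.0, 2.0, 2.25, 3.0]
        concs = [0.0, 9.0, 9.0, 5.0]
        assert compute_cmax_tmax(times, concs) == (9.0, 2.0)

    def test_end_of_infusion_peak_on_day1_schedule(self, one_comp):
        dose = DoseEvent("avibactam", 500.0, 0.0, 2.0)
        t = np.array(DAY1_SCHEDULE)
        c = infusion_concentration(one_comp, dose, t)
        cmax, tmax = compute_cmax_tmax(t, c)
        assert tmax == 2.0
        assert cmax == pytest.approx(infusion_concentration(one_comp, dose, 2.0))


class TestAucLinUpLogDown:
    def test_constant_profile_is_rectangle(self):
        assert auc_lin_up_log_down([0, 2, 5, 8], [10, 10, 10, 10]) == pytest.approx(80.0)

    def test_hand_computed_mixed_segments(self):
        # rise 0->10 linear (5), fall 10->5 log: (10-5)/ln2 = 7.2135
        value = auc_lin_up_log_down([0.0, 1.0, 2.0], [0.0, 10.0, 5.0])
        assert value == pytest.approx(5.0 + 5.0 / math.log(2.0), rel=1e-12)
        assert value == pytest.approx(12.213, abs=5e-4)

    def test_equal_adjacent_concentrations_use_linear_rule(self):
        assert auc_lin_up_log_down([0.0, 1.0], [10.0, 10.0]) == pytest.approx(10.0)

    def test_segment_rules_match_numeric_integration_of_interpolant(self):
        # independent oracle: integrate the piecewise interpolant numerically
        times = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        concs = np.array([0.0, 8.0, 10.0, 4.4, 0.9])

        def interp(t):
            i = np.searchsorted(times, t, side="right") - 1
            i = min(i, len(times) - 2)
            t1, t2, c1, c2 = times[i], times[i + 1], concs[i], concs[i + 1]
            if c2 < c1 and c1 > 0 and c2 > 0:
                return c1 * (c2 / c1) ** ((t - t1) / (t2 - t1))
            return c1 + (c2 - c1) * (t - t1) / (t2 - t1)

        oracle, _ = integrate.quad(interp, 0.0, 8.0, limit=500,
                                   points=list(times))
        assert auc_lin_up_log_down(times, concs) == pytest.approx(oracle, rel=1e-6)

    def test_partial_last_segment_log_interpolated(self):
        # exponential pair: the log rule reproduces the exact sub-area
        lam = 0.25
        times = [0.0, 4.0, 12.0]
        concs = [100.0, 100.0 * math.exp(-lam * 4), 100.0 * math.exp(-lam * 12)]
        got = auc_lin_up_log_down(times, concs, t_end=8.0)
        # both segments fall, so the log rule is exact for the exponential
        exact = (100.0 / lam) * (1.0 - math.exp(-lam * 8.0))
        assert got == pytest.approx(exact, rel=1e-12)

    def test_unsorted_times_rejected(self):
        with pytest.raises(DataError):
            auc_lin_up_log_down([0.0, 2.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        concs=st.lists(st.floats(0.01, 100.0), min_size=4, max_size=10),
        split=st.floats(0.1, 0.9),
    )
    def test_auc_additive_at_arbitrary_split(self, concs, split):
        times = np.arange(len(concs), dtype=float)
        a = times[0] + split * (times[-1] - times[0])
        total = auc_between(times, concs, times[0], times[-1])
        parts = auc_between(times, concs, times[0], a) + \
            auc_between(times, concs, a, times[-1])
        assert parts == pytest.approx(total, abs=1e-10, rel=1e-10)


class TestLambdaZ:
    def test_exact_log_linear_data(self):
        t = np.array([4.0, 6.0, 8.0, 12.0])
        c = 100.0 * np.exp(-0.25 * t)
        fit = fit_lambda_z(t, c, tmax=2.0)
        assert fit.lambda_z == pytest.approx(0.25, rel=1e-12)
        assert fit.rsq == pytest.approx(1.0)
        assert fit.reportable

    def test_selection_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        t = np.array([3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 24.0])
        c = 50.0 * np.exp(-0.3 * t) * np.exp(rng.normal(0.0, 0.05, t.size))
        fit = fit_lambda_z(t, c, tmax=2.0)
        # oracle: exhaustively score every candidate terminal set
        best_adj, best_k = -np.inf, None
        for k in range(3, t.size + 1):
            x, y = t[-k:], np.log(c[-k:])
            slope, intercept = np.polyfit(x, y, 1)
            if slope >= 0:
                continue
            resid = y - (slope * x + intercept)
            rsq = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            adj = 1.0 - (1.0 - rsq) * (k - 1) / (k - 2)
            if adj > best_adj + 1e-4 or (abs(adj - best_adj) <= 1e-4 and (best_k or 0) < k):
                best_adj, best_k = adj, k
        assert fit.n_points == best_k
        assert fit.adj_rsq == pytest.approx(best_adj)

    def test_low_rsq_flagged_not_reportable(self):
        rng = np.random.default_rng(0)
        t = np.array([3.0, 5.0, 8.0, 12.0, 24.0])
        c = np.exp(rng.normal(0.0, 1.0, t.size)) * np.exp(-0.05 * t)
        fit = fit_lambda_z(t, c, tmax=2.0)
        if fit.lambda_z is not None and fit.rsq < 0.8:
            assert not fit.reportable

    def test_too_few_points_not_evaluable(self):
        fit = fit_lambda_z([3.0, 4.0], [5.0, 4.0], tmax=2.0)
        assert not fit.reportable and fit.reason == "insufficient-points"

    def test_rising_terminal_data_not_reportable(self):
        fit = fit_lambda_z([3.0, 4.0, 5.0, 6.0], [1.0, 2.0, 3.0, 4.0], tmax=2.0)
        assert not fit.reportable and fit.reason == "nonnegative-slope"


class TestExtrapolation:
    def test_arithmetic(self):
        auc_inf, frac, ok = extrapolate_auc(98.0, 1.0, 0.5)
        assert auc_inf == pytest.approx(100.0)
        assert frac == pytest.approx(0.02)
        assert ok

    def test_thirty_percent_suppressed(self):
        _, frac, ok = extrapolate_auc(7.0, 0.9, 0.3)
        assert frac == pytest.approx(0.30)
        assert not ok

    def test_noiseless_profile_small_fraction(self, one_comp):
        dose = DoseEvent("x", 500.0, 0.0, 2.0)
        t = np.array(DAY1_SCHEDULE)
        c = infusion_concentration(one_comp, dose, t)
        auc_last = auc_lin_up_log_down(t, c)
        fit = fit_lambda_z(t, c)
        auc_inf, frac, ok = extrapolate_auc(auc_last, c[-1], fit.lambda_z)
        assert ok and frac < 0.01
        assert auc_inf == pytest.approx(500.0 / 12.0, rel=0.01)


class TestNcaProfile:
    def profile(self, params, dose, schedule=DAY1_SCHEDULE):
        t = np.array(schedule)
        c = infusion_concentration(params, dose, t)
        return t, c

    def test_noiseless_profile_recovers_lambda_and_cl(self, one_comp):
        dose = DoseEvent("avibactam", 500.0, 0.0, 2.0)
        t, c = self.profile(one_comp, dose)
        res = nca_profile(t, c, dose=500.0, tau=8.0)
        assert res.lambda_z == pytest.approx(one_comp.terminal_rate, rel=1e-6)
        assert res.cl == pytest.approx(12.0, rel=0.005)
        assert res.half_life == pytest.approx(2.5, rel=1e-6)
        assert res.tmax == 2.0
        assert res.auc_tau < res.auc_last < res.auc_inf

    def test_renal_mass_balance_gives_clr_equal_cl(self, one_comp):
        dose = DoseEvent("avibactam", 500.0, 0.0, 2.0)
        t, c = self.profile(one_comp, dose)
        from crosspk import Regimen, cumulative_urine_amount

        reg = Regimen.single(dose)
        urine = pd.DataFrame([
            {"interval_start": a, "interval_end": b,
             "amount_excreted": cumulative_urine_amount(one_comp, reg, a, b)}
            for a, b in [(0, 2), (2, 4), (4, 8), (8, 12), (12, 24)]
        ])
        res = nca_profile(t, c, dose=500.0, tau=8.0, urine=urine)
        assert res.clr / res.cl == pytest.approx(1.0, abs=0.02)

    def test_all_blq_profile_not_evaluable(self):
        res = nca_profile([0.0, 1.0, 2.0], [np.nan] * 3, [True] * 3, dose=500.0)
        assert res.flags == ("not-evaluable",)
        assert res.cmax is None

    def test_blq_policy_leading_zero_embedded_dropped(self):
        t = [0.0, 1.0, 2.0, 3.0, 4.0, 6.0]
        c = [np.nan, 5.0, np.nan, 8.0, 4.0, 2.0]
        blq = [True, False, True, False, False, False]
        tt, cc = prepare_profile(t, c, blq)
        np.testing.assert_array_equal(tt, [0.0, 1.0, 3.0, 4.0, 6.0])
        np.testing.assert_array_equal(cc, [0.0, 5.0, 8.0, 4.0, 2.0])

    def test_low_rsq_suppresses_auc_inf_halflife_cl(self):
        rng = np.random.default_rng(12)
        t = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 24.0])
        c = np.array([0.0, 30.0, 60.0, 40.0, 0.4, 9.0, 0.2, 1.1])
        res = nca_profile(t, c, dose=500.0, tau=8.0)
        assert res.rsq is None or res.rsq < 0.8
        assert res.auc_inf is None and res.cl is None and res.half_life is None
        assert any(f.startswith("lambda-z") for f in res.flags)
        assert res.cmax is not None and res.auc_tau is not None

    def test_extrapolation_gate_suppresses_but_keeps_auc_tau(self):
        # clean log-linear tail but truncated early -> >20% extrapolated
        lam = 0.08
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0])
        c = np.where(t < 2.0, 50.0 * t, 100.0 * np.exp(-lam * (t - 2.0)))
        res = nca_profile(t, c, dose=500.0, tau=8.0)
        assert res.extrapolated_fraction > 0.20
        assert res.auc_inf is None and res.cl is None
        assert "extrapolated-fraction-above-20pct" in res.flags
        assert res.auc_tau is not None


class TestDerivedRatios:
    def test_printed_table_identities(self):
        day1 = NcaResult(auc_tau=265.0, auc_inf=289.0)
        steady = NcaResult(auc_tau=294.0)
        ratios = accumulation_and_linearity(day1, steady)
        assert round(ratios.accumulation_ratio_auc_tau, 1) == 1.1
        assert round(ratios.linearity_index, 1) == 1.0

    def test_identical_days_give_unity(self):
        r = NcaResult(auc_tau=100.0, auc_inf=110.0)
        ratios = accumulation_and_linearity(r, r)
        assert ratios.accumulation_ratio_auc_tau == 1.0

    def test_missing_inputs_flagged(self):
        ratios = accumulation_and_linearity(NcaResult(auc_tau=100.0),
                                            NcaResult(auc_tau=110.0))
        assert ratios.linearity_index is None
        assert "day1-auc-inf-missing" in ratios.flags


class TestGeometricSummary:
    def test_zero_dispersion(self):
        s = geometric_summary([7.0, 7.0, 7.0])
        assert s.geometric_mean == pytest.approx(7.0)
        assert s.geometric_cv_percent == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        # values e^0, e^2: s = sqrt(2), CV% = 100*sqrt(e^2 - 1)
        s = geometric_summary([1.0, math.exp(2.0)])
        assert s.geometric_cv_percent == pytest.approx(
            100.0 * math.sqrt(math.e**2 - 1.0), rel=1e-12
        )
        assert s.geometric_cv_percent == pytest.approx(252.77, abs=0.05)

    def test_lognormal_sample_converges_to_closed_form(self):
        sigma = 0.2171
        rng = np.random.default_rng(3)
        sample = np.exp(rng.normal(1.0, sigma, 100_000))
        s = geometric_summary(sample)
        expected = 100.0 * math.sqrt(math.expm1(sigma**2))
        assert s.geometric_cv_percent == pytest.approx(expected, rel=0.01)
        assert expected == pytest.approx(21.97, abs=0.05)

    def test_geometric_mean_commutes_with_clearance_identity(self):
        rng = np.random.default_rng(8)
        aucs = np.exp(rng.normal(3.7, 0.2, 40))
        cls = 500.0 / aucs
        gm_cl = geometric_summary(cls).geometric_mean
        gm_auc = geometric_summary(aucs).geometric_mean
        assert gm_cl == pytest.approx(500.0 / gm_auc, rel=1e-12)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(DataError):
            geometric_summary([1.0, 0.0])
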