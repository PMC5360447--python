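"""Exponential reversal fits, inclusion criteria and group statistics."""

import numpy as np
import pytest
from scipy import stats

from photoflex import dynamics as dyn
from photoflex.synthetic import simulate_response_course


def _course(values, rev, sign, n=1):
    return dyn.build_trial_course(values, rev, sign, smoothing_n=n)


class TestMovingAverage:
    def test_constant_unchanged(self):
        assert np.allclose(dyn.moving_average(np.full(20, 3.0), 3), 3.0)

    def test_width_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=30)
        assert np.array_equal(dyn.moving_average(x, 1), x)

    def test_matches_windowed_mean_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        got = dyn.moving_average(x, 3)
        for i in range(50):
            window = x[max(i - 1, 0) : min(i + 2, 50)]
            assert got[i] == pytest.approx(window.mean(), abs=1e-12)

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            dyn.moving_average(np.arange(5.0), 0)


class TestFitReversal:
    def test_noiseless_parameters_recovered(self):
        rng = np.random.default_rng(0)
        vals = simulate_response_course(100, 200, 3.0, 1.0, 50.0, 0.0, rng)
        fit = dyn.fit_reversal(_course(vals, 100, -1))
        assert fit.converged
        assert fit.A == pytest.approx(1.0, rel=1e-3)
        assert fit.B == pytest.approx(2.0, rel=1e-3)
        assert fit.tau == pytest.approx(50.0, rel=1e-3)
        assert fit.pre_level == pytest.approx(3.0, abs=1e-9)

    def test_flat_course_fails_pre_post_difference(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([np.full(100, 2.0), np.full(200, 2.0)]) + rng.normal(0, 0.01, 300)
        fit = dyn.evaluate_course(_course(vals, 100, -1))
        assert fit.included is False
        assert fit.exclusion_reason == "no_pre_post_difference"

    def test_tau_beyond_cap_returned_at_cap_and_flagged(self):
        rng = np.random.default_rng(2)
        vals = simulate_response_course(100, 200, 2.0, 1.0, 300.0, 0.0, rng)
        fit = dyn.fit_reversal(_course(vals, 100, -1), tau_cap=225.0)
        assert fit.tau == 225.0
        assert fit.at_cap

    def test_sign_symmetry(self):
        rng = np.random.default_rng(3)
        vals = simulate_response_course(100, 200, 2.0, 1.0, 40.0, 0.1, rng)
        up = dyn.fit_reversal(_course(-vals, 100, 1))
        down = dyn.fit_reversal(_course(vals, 100, -1))
        assert up.tau == pytest.approx(down.tau, rel=1e-6)
        assert up.A == pytest.approx(-down.A, abs=1e-9)
        assert up.B == pytest.approx(-down.B, abs=1e-9)


class TestInclusion:
    def test_wrong_trend_detected(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(1.0, 0.1, 200)])
        fit = dyn.evaluate_course(_course(vals, 100, -1))  # negative reversal expected
        assert fit.exclusion_reason == "wrong_trend"

    def test_small_tau_excluded_with_reason(self):
        rng = np.random.default_rng(5)
        k = np.arange(1, 201)
        post = np.exp(-k / 0.5) + rng.normal(0, 0.005, 200)
        vals = np.concatenate([rng.normal(1.0, 0.05, 100), post])
        fit = dyn.evaluate_course(_course(vals, 100, -1))
        assert fit.exclusion_reason == "tau_not_gt_1"
        assert fit.tau <= 1.0

    def test_insufficient_trials_flagged(self):
        vals = np.random.default_rng(6).normal(size=60)
        fit = dyn.evaluate_course(_course(vals, 30, -1))
        assert fit.exclusion_reason == "insufficient_trials"

    def test_clean_reversal_included(self):
        rng = np.random.default_rng(7)
        vals = simulate_response_course(100, 200, 2.0, 0.5, 30.0, 0.1, rng)
        fit = dyn.evaluate_course(_course(vals, 100, -1))
        assert fit.included is True
        assert fit.exclusion_reason is None


class TestGroupStatistics:
    def test_identical_groups_have_zero_t(self):
        out = dyn.compare_taus([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == pytest.approx(0.0)

    def test_welch_matches_closed_form(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        out = dyn.compare_taus(a, b)
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert out["t"] == pytest.approx((a.mean() - b.mean()) / se, abs=1e-12)
        ref_t, ref_p = stats.ttest_ind(a, b, equal_var=False)
        assert out["p"] == pytest.approx(ref_p, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            dyn.compare_taus([1.0], [2.0, 3.0])

    def test_anova_matches_f_oracle(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(i, 1.0, 6) for i in range(3)]
        out = dyn.anova_taus(*groups)
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ssb / 2) / (ssw / (18 - 3))
        assert out["F"] == pytest.approx(F, abs=1e-10)

    def test_paired_identical_gives_zero(self):
        out = dyn.paired_tau_difference([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert out["t"] == 0.0 and np.allclose(out["differences"], 0.0)

    def test_paired_constant_nonzero_differences_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            dyn.paired_tau_difference([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_paired_matches_one_sample_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(5, 1, 8), rng.normal(4, 1, 8)
        out = dyn.paired_tau_difference(a, b)
        ref_t, ref_p = stats.ttest_1samp(a - b, 0.0)
        assert out["t"] == pytest.approx(ref_t, abs=1e-12)
        assert out["p"] == pytest.approx(ref_p, abs=1e-12)

    def test_unmatched_pairs_rejected(self):
        with pytest.raises(ValueError, match="matched"):
            dyn.paired_tau_difference([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTauRegression:
    def test_exact_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = dyn.regress_tau(2.0 * x + 1.0, x)
        assert out["slope"] == pytest.approx(2.0, abs=1e-12)
        assert out["intercept"] == pytest.approx(1.0, abs=1e-12)
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert out["n_above_identity"] == 4

    def test_matches_ols_f_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=15)
        y = 1.5 * x + rng.normal(0, 0.5, 15)
        out = dyn.regress_tau(y, x)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - slope * x - intercept
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        F = r2 / ((1 - r2) / 13)
        assert out["slope"] == pytest.approx(slope, abs=1e-10)
        assert out["intercept"] == pytest.approx(intercept, abs=1e-10)
        assert out["r_squared"] == pytest.approx(r2, abs=1e-10)
        assert out["F"] == pytest.approx(F, abs=1e-8)
        assert out["p"] == pytest.approx(stats.f.sf(F, 1, 13), abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            dyn.regress_tau([1.0, 2.0], [1.0, 2.0])


class TestAmplitudeDifference:
    def _fit(self, A, B, tau):
        return dyn.ExpFit(A=A, B=B, tau=tau, converged=True)

    def test_identical_fits_give_zero(self):
        f = self._fit(1.0, 1.0, 30.0)
        assert np.allclose(dyn.fitted_amplitude_difference(f, f, 100), 0.0)

    def test_flat_fits_give_constant(self):
        diff = dyn.fitted_amplitude_difference(
            self._fit(1.0, 0.0, 30.0), self._fit(2.0, 0.0, 60.0), 100
        )
        assert np.allclose(diff, diff[0])

    def test_interior_extremum_matches_calculus_oracle(self):
        tau_f, tau_s, T = 10.0, 80.0, 200
        diff = dyn.fitted_amplitude_difference(
            self._fit(0.0, 1.0, tau_f), self._fit(0.0, 1.0, tau_s), T
        )
        # normalized decreasing curves are affine in exp(-t/tau) with
        # gain c_i = 1/(exp(-1/tau_i) - exp(-T/tau_i)); the difference has
        # a single stationary point at
        # t* = ln(c_f tau_s / (c_s tau_f)) / (1/tau_f - 1/tau_s)
        c_f = 1.0 / (np.exp(-1.0 / tau_f) - np.exp(-T / tau_f))
        c_s = 1.0 / (np.exp(-1.0 / tau_s) - np.exp(-T / tau_s))
        t_star = np.log(c_f * tau_s / (c_s * tau_f)) / (1.0 / tau_f - 1.0 / tau_s)
        idx = int(np.argmin(diff))  # fast decays first: the extremum is a minimum
        assert 0 < idx < T - 1
        assert abs((idx + 1) - t_star) <= 1.0

    def test_nonconverged_input_rejected(self):
        bad = dyn.ExpFit(A=1.0, B=1.0, tau=10.0, converged=False)
        with pytest.raises(ValueError, match="converged"):
            dyn.fitted_amplitude_difference(bad, self._fit(1, 1, 20.0), 50)
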