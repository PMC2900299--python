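"""Growth-curve pipeline tests: logistic fitting, normalization, smoothing,
spline derivatives, clearance metrics, MOI arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phagedyn.curves import (
    CurveError,
    FitError,
    GrowthCurve,
    LogisticFit,
    NormalizedCurve,
    average_replicates,
    clearance_onset,
    common_grid,
    compute_moi,
    derivative_profile,
    fit_logistic,
    logistic,
    moi_difference,
    normalize_curve,
    smooth_curve,
)

T38 = np.linspace(0.2, 11.0, 38)


def make_logistic_curve(K=1.0, mu=0.6, E0=0.02, baseline=0.0, noise_sd=0.0,
                        rng=None, strain="s", condition="uninfected", rep=0):
    y = logistic(T38, K, mu, E0) + baseline
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, size=len(T38))
    return GrowthCurve(strain_id=strain, condition=condition, t=T38.copy(),
                       A=np.maximum(y, 0.0), replicate=rep)


class TestFitLogistic:
    def test_noiseless_self_consistency(self):
        fit = fit_logistic(make_logistic_curve(), baseline=0.0)
        assert fit.K == pytest.approx(1.0, abs=1e-6)
        assert fit.mu == pytest.approx(0.6, abs=1e-6)
        assert fit.E0 == pytest.approx(0.02, abs=1e-6)
        assert fit.rss < 1e-12

    def test_noisy_replicates_recover_parameters(self):
        # 4 replicates, 38 points, additive noise: K and mu within 5%
        ok = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            curves = [make_logistic_curve(noise_sd=0.01, rng=rng, rep=r)
                      for r in range(4)]
            fit = fit_logistic(curves, baseline=0.0)
            if abs(fit.K - 1.0) < 0.05 and abs(fit.mu - 0.6) < 0.03:
                ok += 1
        assert ok >= 0.95 * n_rep

    def test_flat_curve_is_an_error(self):
        flat = GrowthCurve(strain_id="dead", condition="uninfected",
                           t=T38, A=np.full(38, 0.05))
        with pytest.raises(FitError, match="dead"):
            fit_logistic(flat, baseline=0.04)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, c):
        # A -> c*A multiplies K and E0 by c, leaves mu unchanged
        base = fit_logistic(make_logistic_curve(), baseline=0.0)
        curve = make_logistic_curve()
        scaled = GrowthCurve(strain_id="s", condition="uninfected",
                             t=curve.t, A=c * curve.A)
        fit = fit_logistic(scaled, baseline=0.0)
        assert fit.K == pytest.approx(c * base.K, rel=1e-4)
        assert fit.E0 == pytest.approx(c * base.E0, rel=1e-3)
        assert fit.mu == pytest.approx(base.mu, rel=1e-4)

    def test_infected_curve_rejected(self):
        bad = make_logistic_curve(condition="infected")
        with pytest.raises(CurveError):
            fit_logistic(bad)


class TestNormalize:
    def test_identity_transform(self):
        curve = make_logistic_curve()
        fit = LogisticFit(K=1.0, mu=1.0, E0=0.02, rss=0.0, strain_id="s")
        nc = normalize_curve(curve, fit, baseline=0.0)
        np.testing.assert_allclose(nc.tau, curve.t)
        np.testing.assert_allclose(nc.y, curve.A)

    def test_tau_is_mu_times_t(self):
        curve = make_logistic_curve()
        fit = LogisticFit(K=1.0, mu=0.6, E0=0.02, rss=0.0, strain_id="s")
        nc = normalize_curve(curve, fit, baseline=0.0)
        assert np.interp(6.0, nc.tau, nc.tau) == pytest.approx(0.6 * 10.0)

    def test_round_trip_recovers_raw(self):
        curve = make_logistic_curve(K=0.5, mu=0.8, baseline=0.04)
        fit = LogisticFit(K=0.5, mu=0.8, E0=0.01, rss=0.0, strain_id="s")
        nc = normalize_curve(curve, fit, baseline=0.04)
        np.testing.assert_allclose(nc.y * fit.K + 0.04, curve.A, atol=1e-12)
        np.testing.assert_allclose(nc.tau / fit.mu, curve.t, atol=1e-12)

    def test_self_normalization_asymptotes_to_one(self):
        curve = make_logistic_curve(K=0.7, mu=0.9)
        fit = fit_logistic(curve, baseline=0.0)
        nc = normalize_curve(curve, fit, baseline=0.0)
        assert nc.y[-1] == pytest.approx(1.0, abs=0.01)

    def test_strain_mismatch_rejected(self):
        curve = make_logistic_curve(strain="a")
        fit = LogisticFit(K=1, mu=1, E0=0.02, rss=0, strain_id="b")
        with pytest.raises(CurveError):
            normalize_curve(curve, fit)


class TestAverageReplicates:
    def test_single_curve_is_identity(self):
        nc = NormalizedCurve(tau=[0, 1, 2], y=[0.1, 0.2, 0.3], strain_id="s")
        avg = average_replicates([nc])
        np.testing.assert_allclose(np.interp(nc.tau, avg.tau, avg.y), nc.y,
                                   atol=1e-12)

    def test_mean_of_y_and_2y(self):
        tau = np.linspace(0, 5, 20)
        y = np.linspace(0.1, 1.0, 20)
        a = NormalizedCurve(tau=tau, y=y, strain_id="s")
        b = NormalizedCurve(tau=tau, y=2 * y, strain_id="s")
        avg = average_replicates([a, b])
        np.testing.assert_allclose(avg.y, 1.5 * np.interp(avg.tau, tau, y),
                                   atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(CurveError):
            average_replicates([])


class TestSmooth:
    def test_linear_data_unchanged(self):
        tau = np.linspace(0, 10, 50)
        nc = NormalizedCurve(tau=tau, y=0.1 * tau + 0.05, strain_id="s")
        out = smooth_curve(nc, window_frac=0.3)
        np.testing.assert_allclose(out.y, nc.y, atol=1e-8)

    def test_outlier_spike_suppressed(self):
        tau = np.linspace(0, 10, 60)
        clean = 1.0 / (1.0 + np.exp(-(tau - 5)))
        y = clean.copy()
        y[30] += 0.5  # a single bad read
        out = smooth_curve(NormalizedCurve(tau=tau, y=y, strain_id="s"),
                           window_frac=0.2)
        assert abs(out.y[30] - clean[30]) < 0.03

    def test_full_window_linearizes(self):
        tau = np.linspace(0, 10, 30)
        nc = NormalizedCurve(tau=tau, y=2.0 * tau - 1.0, strain_id="s")
        out = smooth_curve(nc, window_frac=1.0)
        np.testing.assert_allclose(out.y, nc.y, atol=1e-8)

    def test_invalid_window(self):
        nc = NormalizedCurve(tau=np.arange(20.0), y=np.arange(20.0))
        with pytest.raises(CurveError):
            smooth_curve(nc, window_frac=0.0)


class TestDerivativeProfile:
    def test_linear_curve_unit_slope(self):
        tau = np.linspace(0, 10, 50)
        nc = NormalizedCurve(tau=tau, y=tau.copy(), strain_id="s")
        prof = derivative_profile(nc, tau)
        np.testing.assert_allclose(prof.dy, 1.0, atol=1e-6)

    def test_constant_curve_zero_slope(self):
        tau = np.linspace(0, 10, 50)
        nc = NormalizedCurve(tau=tau, y=np.full(50, 0.3), strain_id="s")
        prof = derivative_profile(nc, tau)
        np.testing.assert_allclose(prof.dy, 0.0, atol=1e-8)

    def test_logistic_derivative_matches_closed_form(self):
        tau = np.linspace(0, 12, 120)
        E0 = 0.02
        y = E0 / (E0 + (1 - E0) * np.exp(-tau))
        nc = NormalizedCurve(tau=tau, y=y, strain_id="s")
        grid = tau[10:-10]
        prof = derivative_profile(nc, grid)
        yg = E0 / (E0 + (1 - E0) * np.exp(-grid))
        np.testing.assert_allclose(prof.dy, yg * (1 - yg), atol=1e-3)

    def test_integration_round_trip(self):
        tau = np.linspace(0, 12, 150)
        E0 = 0.02
        y = E0 / (E0 + (1 - E0) * np.exp(-tau))
        nc = NormalizedCurve(tau=tau, y=y, strain_id="s")
        prof = derivative_profile(nc, tau)
        rebuilt = y[0] + np.concatenate(
            ([0.0], np.cumsum(np.diff(tau) * 0.5 * (prof.dy[1:] + prof.dy[:-1]))))
        np.testing.assert_allclose(rebuilt, y, atol=1e-3)

    def test_extrapolation_rejected(self):
        tau = np.linspace(0, 5, 20)
        nc = NormalizedCurve(tau=tau, y=tau.copy(), strain_id="s")
        with pytest.raises(CurveError):
            derivative_profile(nc, np.linspace(0, 6, 10))


class TestClearanceOnset:
    def test_monotone_curve_has_no_onset(self):
        tau = np.linspace(0, 10, 50)
        nc = NormalizedCurve(tau=tau, y=1 / (1 + np.exp(-(tau - 5))))
        assert clearance_onset(nc) is None

    def test_constructed_peak(self):
        tau = np.linspace(0, 6, 61)
        y = np.where(tau <= 3.0, 0.55 * tau / 3.0, 0.55 - 0.3 * (tau - 3.0))
        onset = clearance_onset(NormalizedCurve(tau=tau, y=y))
        assert onset == (pytest.approx(3.0), pytest.approx(0.55))

    def test_matches_argmax_on_simulated_infection(self, wt_params, wt_init):
        from phagedyn.model import simulate

        # horizon ends before lysogen regrowth exceeds the pre-crash peak,
        # where a plain argmax is a valid oracle for the clearance peak
        traj = simulate(wt_params, init=wt_init, tau_end=5)
        nc = NormalizedCurve(tau=traj.tau, y=traj.total)
        onset = clearance_onset(nc)
        assert onset is not None
        i_oracle = int(np.argmax(traj.total))
        step = traj.tau[1] - traj.tau[0]
        assert abs(onset[0] - traj.tau[i_oracle]) <= step + 1e-9
        assert onset[1] == pytest.approx(traj.total[i_oracle], abs=1e-6)

    def test_subthreshold_wiggle_ignored(self):
        tau = np.linspace(0, 10, 50)
        y = 0.08 * tau
        y[25:] -= 0.03  # decline smaller than the 0.05 drop threshold
        assert clearance_onset(NormalizedCurve(tau=tau, y=y)) is None


class TestMoiDifference:
    def test_identical_curves_give_zero(self):
        tau = np.linspace(0, 10, 30)
        nc = NormalizedCurve(tau=tau, y=0.1 * tau)
        assert moi_difference(nc, nc) == 0.0

    def test_plain_subtraction(self):
        tau = np.linspace(0, 10, 30)
        low = NormalizedCurve(tau=tau, y=np.full(30, 0.9))
        high = NormalizedCurve(tau=tau, y=np.full(30, 0.4))
        assert moi_difference(high, low, tau_eval=8.0) == pytest.approx(0.5)

    def test_clamp_evaluates_at_largest_shared_tau(self):
        low = NormalizedCurve(tau=np.linspace(0, 7, 20),
                              y=np.linspace(0, 0.7, 20))
        high = NormalizedCurve(tau=np.linspace(0, 9, 20),
                               y=np.linspace(0, 0.2, 20))
        with pytest.raises(CurveError):
            moi_difference(high, low, tau_eval=8.0)
        d = moi_difference(high, low, tau_eval=8.0, clamp=True)
        y_h = np.interp(7.0, high.tau, high.y)
        assert d == pytest.approx(0.7 - y_h)

    def test_entry_blocked_strain_is_moi_invariant(self):
        # kappa = 0 makes the MOI irrelevant to bacterial dynamics
        from phagedyn.model import NondimParams, PopulationState, simulate

        p = NondimParams(kappa=0, b=28, f=0.75)
        lo = simulate(p, init=PopulationState(0.02, 0, 2e-4 * 0.02), tau_end=10)
        hi = simulate(p, init=PopulationState(0.02, 0, 2e-2 * 0.02), tau_end=10)
        d = moi_difference(
            NormalizedCurve(tau=hi.tau, y=hi.total),
            NormalizedCurve(tau=lo.tau, y=lo.total))
        assert abs(d) < 1e-6


class TestComputeMoi:
    def test_standard_inoculation(self):
        # 15 ul of 0.1 OD cells + 15 ul of 1e4 pfu/ml phage
        moi = compute_moi(15, 0.1, 15, 1e4)
        assert moi == pytest.approx(2e-4, rel=1e-9)

    def test_equal_counts_give_unity(self):
        # 1 ml at 5e8 pfu/ml onto 1 ml of 1.0 OD (5e8 cells/ml)
        assert compute_moi(1000, 1.0, 1000, 5e8) == pytest.approx(1.0)

    @given(st.floats(min_value=1.0, max_value=1e3))
    def test_linearity_in_titer(self, factor):
        base = compute_moi(15, 0.1, 15, 1e4)
        assert compute_moi(15, 0.1, 15, 1e4 * factor) == pytest.approx(
            base * factor, rel=1e-9)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(CurveError):
            compute_moi(0, 0.1, 15, 1e4)


def test_common_grid_spans_intersection():
    a = NormalizedCurve(tau=np.linspace(0, 8, 20), y=np.zeros(20))
    b = NormalizedCurve(tau=np.linspace(1, 10, 20), y=np.zeros(20))
    g = common_grid([a, b], n=50)
    assert g[0] == pytest.approx(1.0) and g[-1] == pytest.approx(8.0)
    assert len(g) == 50
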