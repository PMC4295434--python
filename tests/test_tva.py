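"""Whole-report race model: closed forms, likelihood, ML fitting."""

import itertools

import numpy as np
import pytest

from tvasem.synthetic import simulate_whole_report
from tvasem.tva import (
    TvaFit,
    TvaParams,
    WholeReportTrial,
    fit_whole_report,
    laterality_ok,
    score_distribution,
    score_histograms,
    whole_report_loglik,
)


def enumerate_score_distribution(params: TvaParams, exposure_ms: float, n: int = 6) -> np.ndarray:
    """Independent oracle: enumerate all finisher subsets and the K-mixture."""
    t_e = max(0.0, exposure_ms - params.t0) / 1000.0
    p = 1.0 - np.exp(-(params.C / n) * t_e)
    k_lo = int(np.floor(params.K))
    frac = params.K - k_lo
    out = np.zeros(n + 1)
    for finished in itertools.product([0, 1], repeat=n):
        nb = sum(finished)
        prob = p**nb * (1 - p) ** (n - nb)
        for k, wk in ((k_lo, 1 - frac), (min(k_lo + 1, n), frac)):
            if wk > 0:
                out[min(nb, k)] += wk * prob
    return out


class TestScoreDistribution:
    def test_matches_exponential_race_closed_form(self):
        # C=60, K=4, t0=10, exposure 110: each item finishes w.p. 1 - e^-1
        v = score_distribution(TvaParams(60, 4, 10), 110)
        assert v[0] == pytest.approx(np.exp(-6), abs=1e-15)
        oracle = enumerate_score_distribution(TvaParams(60, 4, 10), 110)
        assert np.max(np.abs(v - oracle)) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_for_random_parameters(self, seed):
        r = np.random.default_rng(seed)
        params = TvaParams(r.uniform(5, 120), r.uniform(0.6, 6), r.uniform(0, 40))
        exposure = r.uniform(10, 250)
        v = score_distribution(params, exposure)
        oracle = enumerate_score_distribution(params, exposure)
        assert np.max(np.abs(v - oracle)) < 1e-12
        assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exposure_below_threshold_gives_all_zero_scores(self):
        v = score_distribution(TvaParams(60, 4, 20), 5)
        assert v[0] == 1.0 and np.all(v[1:] == 0)

    def test_fractional_capacity_is_adjacent_integer_mixture(self):
        v35 = score_distribution(TvaParams(60, 3.5, 10), 110)
        v3 = score_distribution(TvaParams(60, 3, 10), 110)
        v4 = score_distribution(TvaParams(60, 4, 10), 110)
        assert np.max(np.abs(v35 - 0.5 * (v3 + v4))) < 1e-12

    def test_no_mass_above_capacity_ceiling(self):
        v = score_distribution(TvaParams(80, 2.3, 0), 200)
        assert np.all(v[4:] == 0)
        assert v[:4].sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("exposures", [(30, 60), (60, 120), (120, 240)])
    def test_stochastically_increasing_in_exposure(self, exposures):
        p = TvaParams(40, 4, 10)
        lo = score_distribution(p, exposures[0])
        hi = score_distribution(p, exposures[1])
        # survival function dominance at every score cut
        for s in range(1, 7):
            assert hi[s:].sum() >= lo[s:].sum() - 1e-12

    def test_stochastically_increasing_in_speed(self):
        slow = score_distribution(TvaParams(20, 4, 10), 110)
        fast = score_distribution(TvaParams(60, 4, 10), 110)
        for s in range(1, 7):
            assert fast[s:].sum() >= slow[s:].sum() - 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            TvaParams(-1, 4, 10)
        with pytest.raises(ValueError):
            TvaParams(60, 0, 10)
        with pytest.raises(ValueError):
            TvaParams(60, 7, 10)
        with pytest.raises(ValueError):
            TvaParams(60, 4, -5)


class TestLoglik:
    def test_single_zero_score_trial_closed_form(self):
        # P(score 0) = e^-6 so the loglik of one such trial is exactly -6
        ll = whole_report_loglik(TvaParams(60, 4, 10), {110.0: [1, 0, 0, 0, 0, 0, 0]})
        assert ll == pytest.approx(-6.0, abs=1e-12)

    def test_certain_outcome_gives_zero_loglik(self):
        ll = whole_report_loglik(TvaParams(60, 4, 50), {20.0: [10, 0, 0, 0, 0, 0, 0]})
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_loglik_is_finite_even_for_impossible_counts(self):
        ll = whole_report_loglik(TvaParams(60, 4, 50), {20.0: [0, 0, 0, 0, 0, 0, 3]})
        assert np.isfinite(ll) and ll < -50

    def test_maximized_near_generating_parameters(self):
        true = TvaParams(50, 3.5, 15)
        trials = simulate_whole_report(true, [20, 50, 80, 140, 200], 300, seed=5)
        counts = score_histograms(trials)
        ll_true = whole_report_loglik(true, counts)
        for params in [TvaParams(30, 3.5, 15), TvaParams(50, 2.5, 15), TvaParams(50, 3.5, 60)]:
            assert whole_report_loglik(params, counts) < ll_true

    def test_bad_histograms_rejected(self):
        with pytest.raises(ValueError):
            whole_report_loglik(TvaParams(60, 4, 10), {})
        with pytest.raises(ValueError):
            whole_report_loglik(TvaParams(60, 4, 10), {110.0: [0] * 7})
        with pytest.raises(ValueError):
            whole_report_loglik(TvaParams(60, 4, 10), {110.0: [1, 0, 0]})


class TestFitWholeReport:
    def test_recovers_generating_parameters(self):
        true = TvaParams(43.21, 3.58, 21.9)
        trials = simulate_whole_report(true, [10, 30, 60, 110, 200], 200, seed=3)
        fit = fit_whole_report(trials, bounds={"t0": (0.0, 200.0)})
        assert fit.converged
        assert fit.params.C == pytest.approx(true.C, rel=0.15)
        assert fit.params.K == pytest.approx(true.K, rel=0.08)
        assert fit.params.t0 == pytest.approx(true.t0, abs=8.0)

    def test_refit_is_deterministic(self):
        trials = simulate_whole_report(TvaParams(40, 3, 20), [50, 100, 200], 60, seed=9)
        f1 = fit_whole_report(trials)
        f2 = fit_whole_report(trials)
        assert (f1.params.C, f1.params.K, f1.params.t0) == (f2.params.C, f2.params.K, f2.params.t0)
        assert f1.loglik == f2.loglik

    def test_trial_order_does_not_matter(self):
        trials = simulate_whole_report(TvaParams(40, 3, 20), [50, 100, 200], 60, seed=9)
        rev = list(reversed(trials))
        f1, f2 = fit_whole_report(trials), fit_whole_report(rev)
        assert f1.params == f2.params and f1.loglik == pytest.approx(f2.loglik)

    def test_ceiling_performance_pins_capacity_at_six(self):
        letters = "ABDEFG"
        trials = [
            WholeReportTrial("p", e, letters, letters)
            for e in (100.0, 200.0)
            for _ in range(60)
        ]
        fit = fit_whole_report(trials)
        assert fit.params.K == pytest.approx(6.0)
        assert fit.at_bounds

    def test_all_zero_scores_is_boundary_fit(self):
        trials = [
            WholeReportTrial("p", e, "ABDEFG", "") for e in (20.0, 50.0) for _ in range(40)
        ]
        with pytest.warns(UserWarning):
            fit = fit_whole_report(trials)
        assert fit.converged and fit.at_bounds
        assert fit.laterality_index is None

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            fit_whole_report([])


class TestLaterality:
    def _fit(self, index):
        return TvaFit(TvaParams(40, 3, 20), -1.0, True, 100, index)

    def test_ratio_arithmetic(self):
        # 40 left of 100 correct reports
        assert laterality_ok(self._fit(40 / 100))

    @pytest.mark.parametrize(
        "index,ok",
        [(1.0, False), (0.0, False), (0.3, True), (0.7, True), (0.29, False), (0.5, True)],
    )
    def test_inclusive_bounds(self, index, ok):
        assert laterality_ok(self._fit(index)) is ok

    def test_undefined_index_fails(self):
        assert laterality_ok(self._fit(None)) is False

    def test_left_counting_uses_display_halves(self):
        t = WholeReportTrial("p", 100, "ABDEFG", "ABG")
        assert t.n_left_correct == 2 and t.score == 3
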