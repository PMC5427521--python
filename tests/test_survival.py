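import math

import numpy as np
import pytest
from scipy import optimize

from relscale.survival import (
    cox_binary,
    cox_partial_loglik,
    cox_score_test_at_null,
    km_estimate,
    logrank,
)
from tests.conftest import make_ipd


def reference_partial_loglik(beta, times, events, group, ties):
    """Independent partial log-likelihood, written directly from the ties
    formulas (no shared code with the fitted implementation)."""
    ll = 0.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        dead = [i for i, (ti, ei) in enumerate(zip(times, events)) if ei and ti == t]
        risk = [i for i, ti in enumerate(times) if ti >= t]
        d = len(dead)
        s_dead = sum(group[i] for i in dead)
        ll += beta * s_dead
        exps = [math.exp(beta * group[i]) for i in risk]
        if ties == "breslow":
            ll -= d * math.log(sum(exps))
        else:
            tied_exps = sum(math.exp(beta * group[i]) for i in dead)
            for j in range(d):
                ll -= math.log(sum(exps) - j / d * tied_exps)
    return ll


def grid_optimum(times, events, group, ties):
    res = optimize.minimize_scalar(
        lambda b: -reference_partial_loglik(b, times, events, group, ties),
        bounds=(-8, 8),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return res.x


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self):
        km = km_estimate([1, 2, 3])
        assert km.times.tolist() == [1, 2, 3]
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # [1, 2+, 3]: S(1) = 2/3; censoring at 2 drops no survival;
        # the last subject's event takes S to 0
        km = km_estimate([1, 2, 3], [False, True, False])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        km = km_estimate([2, 4, 6], [True, True, True])
        assert km.all_censored
        assert (km.survival == 1.0).all()

    def test_ecdf_property_random_sample(self, rng):
        x = rng.integers(1, 12, size=30).astype(float)
        km = km_estimate(x)
        for t in km.times:
            assert km.survival_at(t) == pytest.approx(np.mean(x > t))


class TestLogrank:
    def test_identical_arms_null(self):
        res = logrank(make_ipd([1, 2, 3], [1, 2, 3]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_matches_hand_computation(self):
        # arms {1,2} vs {3,4}: per event time the 2x2 hypergeometric sums
        # give O - E = 2 - (1/2 + 1/3) = 7/6 and V = 1/4 + 2/9 = 17/36,
        # so chi2 = (7/6)^2 / (17/36)
        res = logrank(make_ipd([1, 2], [3, 4]))
        expected = (7 / 6) ** 2 / (17 / 36)
        assert res.statistic == pytest.approx(expected, rel=1e-9)

    def test_label_swap_invariance(self, multiplicative_ipd):
        fwd = logrank(multiplicative_ipd)
        swapped = make_ipd(
            multiplicative_ipd.arm_durations("control"),
            multiplicative_ipd.arm_durations("treated"),
        )
        assert logrank(swapped).statistic == pytest.approx(fwd.statistic, rel=1e-9)

    def test_all_censored_rejected(self):
        ipd = make_ipd([1, 2], [3, 4], censored_a=[True, True],
                       censored_b=[True, True])
        with pytest.raises(ValueError):
            logrank(ipd)

    def test_power_under_multiplicative_effect(self):
        # with a true 25% reduction and 50 patients/arm the logrank should
        # reject in the majority of trials
        from relscale.synthetic_trials import TrialConfig, simulate_trial

        rejections = sum(
            logrank(simulate_trial(
                TrialConfig(seed=1000 + i, ratio=0.75)
            ).ipd).p_value < 0.05
            for i in range(20)
        )
        assert rejections > 10


class TestCoxBinary:
    # interleaved event times so the partial likelihood has a finite optimum
    toy_times = [1.0, 2.0, 4.0, 5.0, 7.0, 9.0]
    toy_group = [1, 0, 1, 0, 1, 0]

    def _toy_ipd(self):
        treated = [t for t, g in zip(self.toy_times, self.toy_group) if g]
        control = [t for t, g in zip(self.toy_times, self.toy_group) if not g]
        return make_ipd(treated, control)

    def test_exchangeable_arms_rr_one(self):
        ipd = make_ipd([2, 5, 9], [2, 5, 9])
        for ties in ("efron", "breslow"):
            fit = cox_binary(ipd, ties=ties)
            assert fit.converged
            assert fit.rr == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_tie_free_toy_matches_grid_search(self, ties):
        ipd = self._toy_ipd()
        fit = cox_binary(ipd, ties=ties)
        events = [True] * 6
        ref = grid_optimum(self.toy_times, events, self.toy_group, ties)
        assert fit.log_hr == pytest.approx(ref, abs=1e-6)

    def test_tied_time_separates_ties_methods(self):
        times = [1.0, 4.0, 7.0, 4.0, 5.0, 9.0]
        ipd = make_ipd(times[:3], times[3:])
        events = [True] * 6
        group = [1, 1, 1, 0, 0, 0]
        fits = {}
        for ties in ("efron", "breslow"):
            fit = cox_binary(ipd, ties=ties)
            ref = grid_optimum(times, events, group, ties)
            assert fit.log_hr == pytest.approx(ref, abs=1e-6)
            fits[ties] = fit.log_hr
        assert fits["efron"] != pytest.approx(fits["breslow"], abs=1e-4)

    def test_fit_never_worse_than_null(self, multiplicative_ipd):
        times = np.array([r.duration for r in multiplicative_ipd.records])
        events = np.array([not r.censored for r in multiplicative_ipd.records])
        group = np.array(
            [1.0 if r.arm == "treated" else 0.0 for r in multiplicative_ipd.records]
        )
        for ties in ("efron", "breslow"):
            fit = cox_binary(multiplicative_ipd, ties=ties)
            at_fit = cox_partial_loglik(fit.log_hr, times, events, group, ties)
            at_null = cox_partial_loglik(0.0, times, events, group, ties)
            assert at_fit >= at_null

    def test_score_test_equals_logrank_on_tie_free_data(self):
        # continuous simulated durations are tie-free almost surely
        from relscale.synthetic_trials import TrialConfig, simulate_trial

        ipd = simulate_trial(TrialConfig(seed=5, ratio=0.8, n_treated=30,
                                         n_control=30)).ipd
        score = cox_score_test_at_null(ipd, ties="breslow")
        lr = logrank(ipd)
        assert score.statistic == pytest.approx(lr.statistic, rel=1e-9)

    def test_matches_lifelines_efron(self, multiplicative_ipd):
        lifelines = pytest.importorskip("lifelines")
        fit = cox_binary(multiplicative_ipd, ties="efron")
        df = multiplicative_ipd.to_frame()
        df["group"] = (df["arm"] == "treated").astype(float)
        df["event"] = 1 - df["censored"]
        cph = lifelines.CoxPHFitter()
        cph.fit(df[["duration", "group", "event"]], duration_col="duration",
                event_col="event")
        assert fit.log_hr == pytest.approx(cph.params_["group"], abs=1e-5)
        assert fit.se == pytest.approx(cph.standard_errors_["group"], abs=1e-5)

    def test_monotone_likelihood_flagged(self):
        # complete separation: every treated event precedes every control one
        ipd = make_ipd([1, 2, 3], [10, 11, 12])
        fit = cox_binary(ipd)
        assert not fit.converged
        assert fit.ci_high == math.inf

    def test_censoring_respected(self):
        uncensored = make_ipd([2, 4, 6], [3, 5, 9])
        censored = make_ipd([2, 4, 6], [3, 5, 9], censored_a=[False, False, True])
        a = cox_binary(uncensored)
        b = cox_binary(censored)
        assert a.log_hr != pytest.approx(b.log_hr, abs=1e-6)
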