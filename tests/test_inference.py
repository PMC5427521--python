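import itertools
import math

import numpy as np
import pytest
from scipy import stats

from relscale.data_model import ArmSummary, TrialSummary, summarize_ipd
from relscale.inference import (
    ci_bootstrap,
    ci_fieller,
    ci_log_t,
    ci_normalized_t,
    ci_taylor,
    permutation_test,
    two_sample_t,
    variance_ratio_test,
)
from tests.conftest import make_ipd


class TestVarianceRatioTest:
    def test_published_p_values(self, mossad, petrus):
        # placebo vs zinc arm SDs in both trials
        pm = variance_ratio_test(mossad.control, mossad.treated)
        assert pm.p_value == pytest.approx(2e-5, abs=1e-5)
        pp = variance_ratio_test(petrus.control, petrus.treated)
        assert pp.p_value == pytest.approx(0.004, abs=0.0005)

    def test_identical_arms(self):
        arm = ArmSummary("a", 20, 6.0, 2.0)
        arm2 = ArmSummary("b", 20, 6.0, 2.0)
        r = variance_ratio_test(arm, arm2)
        assert r.statistic == 1.0
        assert r.p_value == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self, mossad):
        fwd = variance_ratio_test(mossad.control, mossad.treated)
        rev = variance_ratio_test(mossad.treated, mossad.control)
        assert fwd.statistic == pytest.approx(1 / rev.statistic, rel=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-9)

    def test_matches_scipy_f_distribution(self, mossad):
        r = variance_ratio_test(mossad.control, mossad.treated)
        f = (mossad.control.sd / mossad.treated.sd) ** 2
        assert r.p_value == pytest.approx(2 * stats.f.sf(f, 49, 48), rel=1e-9)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            variance_ratio_test(ArmSummary("a", 5, 4, 0.0), ArmSummary("b", 5, 4, 1.0))


class TestTwoSampleT:
    def test_identical_samples(self):
        r = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_scipy(self, rng, equal_var):
        x = rng.gamma(4, 1.5, size=30)
        y = rng.gamma(4, 2.0, size=35)
        mine = two_sample_t(x, y, equal_var=equal_var)
        ref = stats.ttest_ind(x, y, equal_var=equal_var)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_separated_constant_samples(self):
        r = two_sample_t([2.0, 2.0], [1.0, 1.0])
        assert r.p_value == 0.0

    def test_summary_t_matches_raw_t(self, multiplicative_ipd):
        from relscale.inference import two_sample_t_from_summaries

        x = multiplicative_ipd.arm_durations("treated")
        y = multiplicative_ipd.arm_durations("control")
        tr = summarize_ipd(multiplicative_ipd, treated_arm="treated")
        raw = two_sample_t(x, y)
        summ = two_sample_t_from_summaries(tr.treated, tr.control)
        assert summ.statistic == pytest.approx(raw.statistic, rel=1e-9)


class TestPermutationTest:
    def test_exchangeable_arms(self):
        assert permutation_test(make_ipd([1, 2, 3], [1, 2, 3])).p_value == 1.0

    def test_tiny_exact_enumeration(self):
        # {1,2} vs {10,11}: only the observed split and its mirror reach
        # |difference| 9, so p = 2/6
        p = permutation_test(make_ipd([1, 2], [10, 11])).p_value
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_exact_equals_brute_force(self, rng):
        x = rng.integers(1, 15, size=5).astype(float)
        y = rng.integers(1, 15, size=6).astype(float)
        res = permutation_test(make_ipd(x, y))
        assert res.method == "permutation-exact"
        pooled = np.concatenate([x, y])
        obs = abs(x.mean() - y.mean())
        n1, n = len(x), len(pooled)
        hits = total = 0
        for comb in itertools.combinations(range(n), n1):
            a = pooled[list(comb)]
            b = np.delete(pooled, list(comb))
            total += 1
            if abs(a.mean() - b.mean()) >= obs - 1e-12:
                hits += 1
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_mc_consistent_with_exact(self):
        ipd = make_ipd([2, 5, 9], [4, 7, 12])
        exact = permutation_test(ipd).p_value
        mc = permutation_test(ipd, max_exact_n=1, reps=100_000, seed=11)
        assert mc.method == "permutation-mc"
        se = math.sqrt(exact * (1 - exact) / 100_000)
        assert mc.p_value == pytest.approx(exact, abs=3 * se + 2e-5)

    def test_low_reps_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(make_ipd([1, 2], [3, 4]), max_exact_n=1, reps=10)


class TestCiLogT:
    def test_exact_multiplicative_shift(self):
        base = [2.0, 4.0, 6.0, 9.0, 3.0]
        ipd = make_ipd([0.75 * v for v in base], base)
        iv = ci_log_t(ipd)
        # log-difference of an exact x0.75 copy is constant, so the interval
        # is centred exactly on -25% with width from the common within-arm spread
        mid = 100 * (math.exp((math.log(iv.low / 100 + 1)
                               + math.log(iv.high / 100 + 1)) / 2) - 1)
        assert mid == pytest.approx(-25.0, abs=1e-9)

    def test_width_shrinks_with_spread(self):
        tight = make_ipd([3.0, 3.01, 2.99], [4.0, 4.01, 3.99])
        loose = make_ipd([1.0, 3.0, 9.0], [2.0, 4.0, 12.0])
        assert ci_log_t(tight).width < ci_log_t(loose).width

    def test_nonpositive_duration_rejected(self):
        # IPDTrial itself forbids durations <= 0, so the guard is exercised
        # on raw arrays through the underlying check
        with pytest.raises(ValueError):
            make_ipd([0.0, 2.0], [3.0, 4.0])


class TestCiTaylor:
    def test_inside_normalized_interval(self, mossad, petrus):
        for trial in (mossad, petrus):
            nt = ci_normalized_t(trial)
            ty = ci_taylor(trial)
            assert nt.low < ty.low and ty.high < nt.high

    def test_symmetric_null_contains_zero(self):
        tr = TrialSummary(
            treated=ArmSummary("t", 30, 6.0, 2.0),
            control=ArmSummary("c", 30, 6.0, 2.0),
        )
        iv = ci_taylor(tr)
        assert iv.low < 0 < iv.high

    def test_interval_shrinks_with_n(self, petrus):
        big = TrialSummary(
            treated=ArmSummary("t", 52_000, petrus.treated.mean, petrus.treated.sd),
            control=ArmSummary("c", 49_000, petrus.control.mean, petrus.control.sd),
        )
        assert ci_taylor(big).width < ci_taylor(petrus).width / 10


class TestCiFieller:
    def test_inside_normalized_interval(self, mossad, petrus):
        for trial in (mossad, petrus):
            nt = ci_normalized_t(trial)
            fi = ci_fieller(trial)
            assert not fi.unbounded
            assert nt.low < fi.low and fi.high < nt.high

    def test_identical_arms_contain_zero(self):
        tr = TrialSummary(
            treated=ArmSummary("t", 30, 6.0, 2.0),
            control=ArmSummary("c", 30, 6.0, 2.0),
        )
        iv = ci_fieller(tr)
        assert iv.low < 0 < iv.high

    def test_small_variance_limit_agrees_with_taylor(self):
        # with tiny SEs the ratio is nearly linear and Fieller converges to
        # the delta method
        tr = TrialSummary(
            treated=ArmSummary("t", 5000, 5.0, 0.1),
            control=ArmSummary("c", 5000, 8.0, 0.1),
        )
        fi, ty = ci_fieller(tr), ci_taylor(tr)
        assert fi.low == pytest.approx(ty.low, rel=5e-4)
        assert fi.high == pytest.approx(ty.high, rel=5e-4)

    def test_noisy_denominator_flagged_unbounded(self):
        tr = TrialSummary(
            treated=ArmSummary("t", 3, 5.0, 1.0),
            control=ArmSummary("c", 3, 1.0, 40.0),
        )
        assert ci_fieller(tr).unbounded


class TestCiBootstrap:
    def test_same_seed_identical(self, multiplicative_ipd):
        a = ci_bootstrap(multiplicative_ipd, scheme="ratio", reps=999, seed=5)
        b = ci_bootstrap(multiplicative_ipd, scheme="ratio", reps=999, seed=5)
        assert (a.low, a.high) == (b.low, b.high)

    def test_different_seeds_differ(self, multiplicative_ipd):
        a = ci_bootstrap(multiplicative_ipd, reps=999, seed=5)
        b = ci_bootstrap(multiplicative_ipd, reps=999, seed=6)
        assert (a.low, a.high) != (b.low, b.high)

    def test_degenerate_arms_zero_width(self):
        ipd = make_ipd([3.0, 3.0, 3.0], [4.0, 4.0, 4.0])
        iv = ci_bootstrap(ipd, scheme="ratio", reps=999, seed=1)
        assert iv.low == iv.high == pytest.approx(100 * (3 / 4 - 1))

    def test_low_reps_rejected(self, multiplicative_ipd):
        with pytest.raises(ValueError):
            ci_bootstrap(multiplicative_ipd, reps=500, seed=1)

    def test_unknown_scheme_rejected(self, multiplicative_ipd):
        with pytest.raises(ValueError):
            ci_bootstrap(multiplicative_ipd, scheme="wild", reps=999, seed=1)

    def test_both_schemes_bracket_point_estimate(self, multiplicative_ipd):
        tr = summarize_ipd(multiplicative_ipd, treated_arm="treated")
        point = 100 * (tr.treated.mean / tr.control.mean - 1)
        for scheme in ("ratio", "normalized-difference"):
            iv = ci_bootstrap(multiplicative_ipd, scheme=scheme, reps=1999, seed=2)
            assert iv.low < point < iv.high

    def test_ratio_scheme_agrees_with_scipy_bca(self):
        # equal arm sizes let scipy's paired-sample BCa machinery express the
        # same ratio statistic; the two implementations should agree closely
        pytest.importorskip("scipy", minversion="1.10")
        rng = np.random.default_rng(42)
        x = rng.gamma(4, 1.0, size=40)
        y = rng.gamma(4, 1.4, size=40)
        ipd = make_ipd(x, y)
        mine = ci_bootstrap(ipd, scheme="ratio", reps=9999, seed=7)

        def stat(xx, yy, axis=-1):
            return 100 * (np.mean(xx, axis=axis) / np.mean(yy, axis=axis) - 1)

        ref = stats.bootstrap(
            (x, y), stat, n_resamples=9999, method="BCa", paired=False,
            random_state=np.random.default_rng(7), confidence_level=0.95,
        )
        assert mine.low == pytest.approx(ref.confidence_interval.low, abs=1.0)
        assert mine.high == pytest.approx(ref.confidence_interval.high, abs=1.0)


class TestLevelMonotonicity:
    def test_raising_level_never_narrows(self, petrus, multiplicative_ipd):
        constructors = [
            lambda lv: ci_normalized_t(petrus, level=lv),
            lambda lv: ci_taylor(petrus, level=lv),
            lambda lv: ci_fieller(petrus, level=lv),
            lambda lv: ci_log_t(multiplicative_ipd, level=lv),
            lambda lv: ci_bootstrap(multiplicative_ipd, reps=999, seed=3, level=lv),
        ]
        for make in constructors:
            widths = [make(lv).width for lv in (0.80, 0.90, 0.95, 0.99)]
            assert all(b >= a for a, b in zip(widths, widths[1:]))
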