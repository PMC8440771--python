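"""Statistical battery: effect sizes, count models, paired tests, survival."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test as ll_logrank

import sleepdrive as sd
from sleepdrive.oculomotor import SurvivalRecord
from sleepdrive.stats import EffectSizeInput, round_half_up


class TestHedgesG:
    @pytest.mark.parametrize("m1,s1,m2,s2,n,expected", [
        (14.47, 13.32, 5.00, 7.02, 17, 0.79),
        (1.68, 2.93, 0.63, 1.01, 19, 0.43),
    ])
    def test_published_comparisons_reproduced(self, m1, s1, m2, s2, n,
                                              expected):
        g = sd.hedges_g_adj(EffectSizeInput(m1, s1, m2, s2, n))
        assert round_half_up(g, 2) == expected

    def test_equal_means_give_zero(self):
        assert sd.hedges_g_adj(EffectSizeInput(5.0, 2.0, 5.0, 3.0, 10)) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(0.1, 20), st.floats(-50, 50),
           st.floats(0.1, 20), st.integers(4, 40), st.floats(0.01, 100))
    def test_antisymmetry_and_scale_invariance(self, m1, s1, m2, s2, n, a):
        g = sd.hedges_g_adj(EffectSizeInput(m1, s1, m2, s2, n))
        g_swapped = sd.hedges_g_adj(EffectSizeInput(m2, s2, m1, s1, n))
        assert g == pytest.approx(-g_swapped, rel=1e-12, abs=1e-12)
        g_scaled = sd.hedges_g_adj(
            EffectSizeInput(a * m1, a * s1, a * m2, a * s2, n))
        assert g == pytest.approx(g_scaled, rel=1e-9, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="N < 4"):
            sd.hedges_g_adj(EffectSizeInput(1, 1, 0, 1, 3))
        with pytest.raises(ValueError, match="zero"):
            sd.hedges_g_adj(EffectSizeInput(1, 0, 0, 0, 10))


class TestSampleSize:
    def test_reaction_time_design_needs_14(self):
        assert sd.sample_size_mean_change(50.0, 65.0, 0.80, 0.05) == 14

    def test_unit_effect_size_needs_8(self):
        assert sd.sample_size_mean_change(65.0, 65.0, 0.80, 0.05) == 8

    def test_doubling_sd_quadruples_n(self):
        n1 = sd.sample_size_mean_change(10.0, 40.0)
        n4 = sd.sample_size_mean_change(10.0, 80.0)
        assert n4 == pytest.approx(4 * n1, abs=3)  # up to ceiling effects

    def test_power_not_exceeding_half_alpha_rejected(self):
        with pytest.raises(ValueError, match="power"):
            sd.sample_size_mean_change(50.0, 65.0, power=0.02, alpha=0.05)


def _wilcoxon_enumeration_p(diffs: np.ndarray) -> float:
    """Exact two-sided p by brute force over all sign assignments."""
    d = diffs[diffs != 0]
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    v_obs = ranks[d > 0].sum()
    n = len(d)
    # each sign assignment marks which differences are positive
    vs = np.array([float(np.sum(ranks * np.array(signs)))
                   for signs in itertools.product([0, 1], repeat=n)])
    p = 2 * min((vs <= v_obs).mean(), (vs >= v_obs).mean())
    return min(p, 1.0)


class TestWilcoxon:
    def test_all_positive_differences_exact_tail(self):
        res = sd.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.statistic == 15.0
        assert res.p == pytest.approx(2 / 32)

    def test_antisymmetric_differences_land_in_null_region(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sd.wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0])
        assert res.p > 0.8

    def test_exact_p_matches_full_enumeration(self, rng):
        for _ in range(5):
            d = rng.normal(0.3, 1.0, 12)
            res = sd.wilcoxon_signed_rank(d)
            assert res.p == pytest.approx(_wilcoxon_enumeration_p(d),
                                          abs=1e-10)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sd.wilcoxon_signed_rank([0.0, 0.0, 0.0])


class TestNBModels:
    def _paired_frame(self, manual, selfdriving):
        n = len(manual)
        return pd.DataFrame({
            "subject": np.repeat(np.arange(n), 2),
            "condition": ["manual", "self-driving"] * n,
            "count": np.column_stack([manual, selfdriving]).ravel(),
        })

    def test_identical_counts_give_null_rate_ratio(self, rng):
        c = rng.poisson(5, 30)
        res = sd.nb_repeated_condition(self._paired_frame(c, c))
        assert abs(res.estimate) < 1e-6
        assert res.wald_chi2 < 1e-6

    def test_rate_ratio_recovery(self, rng):
        n = 200
        lam = rng.gamma(1.0, 1.0, size=n)
        manual = rng.poisson(3.0 * lam)
        selfd = rng.poisson(6.0 * lam)
        res = sd.nb_repeated_condition(self._paired_frame(manual, selfd))
        assert 1.8 <= res.rate_ratio <= 2.2
        assert res.ci_low <= np.log(2.0) <= res.ci_high

    def test_all_zero_condition_warns(self, rng):
        manual = np.zeros(20, dtype=int)
        selfd = rng.poisson(3, 20)
        with pytest.warns(UserWarning, match="all-zero"):
            sd.nb_repeated_condition(self._paired_frame(manual, selfd))

    def test_unpaired_subjects_rejected(self):
        df = pd.DataFrame({"subject": [0, 0, 1],
                           "condition": ["manual", "self-driving",
                                         "manual"],
                           "count": [1, 2, 3]})
        with pytest.raises(ValueError, match="exactly one"):
            sd.nb_repeated_condition(df)

    def test_sleep_slope_recovery(self, rng):
        sleep = rng.normal(5.9, 0.9, 200)
        mu = 5.0 * np.exp(-0.5 * (sleep - 5.9))
        counts = rng.poisson(rng.gamma(2.0, mu / 2.0))
        res = sd.nb_sleep_slope(counts, sleep)
        assert res.ci_low <= -0.5 <= res.ci_high
        assert res.estimate == pytest.approx(-0.5, abs=0.25)

    def test_sleep_slope_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            sd.nb_sleep_slope([1, 2, 3], [6.0, 6.0, 6.0])
        with pytest.raises(ValueError, match="zero variance"):
            sd.nb_sleep_slope([2, 2, 2], [5.0, 6.0, 7.0])


def _records(times_m, times_s, events_m=None, events_s=None):
    out = []
    for i, (tm, ts) in enumerate(zip(times_m, times_s)):
        em = 1 if events_m is None else events_m[i]
        es = 1 if events_s is None else events_s[i]
        out.append(SurvivalRecord(f"S{i}", "manual", tm, em))
        out.append(SurvivalRecord(f"S{i}", "self-driving", ts, es))
    return out


class TestPairedLogrank:
    def test_identical_event_times_give_null_statistic(self):
        t = np.linspace(100, 2000, 15)
        res = sd.paired_logrank(_records(t, t))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_strong_separation_detected(self, rng):
        tm = rng.uniform(2000, 2800, 20)
        ts = rng.uniform(100, 600, 20)
        res = sd.paired_logrank(_records(tm, ts))
        assert res.p < 0.01

    def test_all_censored_rejected(self):
        recs = _records([100, 200], [300, 400],
                        events_m=[0, 0], events_s=[0, 0])
        with pytest.raises(ValueError, match="no events"):
            sd.paired_logrank(recs)

    def test_single_stratum_matches_lifelines(self, rng):
        # all records in one stratum: our statistic must equal the
        # standard unstratified log-rank from lifelines
        tm = rng.exponential(1000, 30)
        ts = rng.exponential(600, 30)
        cm, cs = tm < 2880, ts < 2880
        recs = [SurvivalRecord("S0", "manual", min(t, 2880), int(e))
                for t, e in zip(tm, cm)]
        recs += [SurvivalRecord("S0", "self-driving", min(t, 2880), int(e))
                 for t, e in zip(ts, cs)]
        res = sd.paired_logrank(recs)
        ll = ll_logrank(np.minimum(tm, 2880), np.minimum(ts, 2880),
                        event_observed_A=cm.astype(int),
                        event_observed_B=cs.astype(int))
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-6)
        assert res.p == pytest.approx(ll.p_value, rel=1e-6)


class TestMixedModel:
    def _frame(self, manual, selfd):
        n = len(manual)
        return pd.DataFrame({
            "subject": np.repeat(np.arange(n), 2),
            "condition": ["manual", "self-driving"] * n,
            "value": np.column_stack([manual, selfd]).ravel(),
        })

    def test_balanced_data_equals_paired_ttest(self, rng):
        base = rng.normal(300, 40, 20)
        manual = base + rng.normal(0, 15, 20)
        selfd = base + 20 + rng.normal(0, 15, 20)
        mm = sd.mixed_random_intercept(self._frame(manual, selfd))
        tt = sd.paired_ttest(selfd, manual)
        assert mm.p == pytest.approx(tt.p, abs=1e-6)
        assert mm.estimate == pytest.approx(tt.estimate, abs=1e-6)

    def test_null_effect_unbiased(self, rng):
        hits = 0
        for _ in range(100):
            base = rng.normal(0, 30, 12)
            manual = base + rng.normal(0, 10, 12)
            selfd = base + rng.normal(0, 10, 12)
            res = sd.mixed_random_intercept(self._frame(manual, selfd))
            se = abs(res.estimate / res.statistic) if res.statistic else 1.0
            hits += abs(res.estimate) < 2 * se
        assert hits >= 85  # ~95% expected under the null

    def test_singular_fit_falls_back_to_paired_t(self, rng):
        # anti-correlated pairs (negative between-subject covariance) push
        # the random-intercept variance to the REML boundary
        manual = rng.normal(0, 1, 15)
        selfd = 5.0 - manual
        with pytest.warns(UserWarning, match="paired t-test"):
            res = sd.mixed_random_intercept(self._frame(manual, selfd))
        assert "fallback" in res.note
        assert res.p < 0.01


class TestPairedT:
    def test_identical_samples_zero_statistic(self):
        x = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match="zero variance"):
            sd.paired_ttest(x, x)

    def test_closed_form_example(self):
        res = sd.paired_ttest([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=1e-4)
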