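"""Kaplan-Meier estimation, lifespan summaries, log-rank, Fisher's exact."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from nemaquant import (
    KMCurve,
    SurvivalRecord,
    SurvivalSimConfig,
    fisher_exact,
    km_estimate,
    lifespan_pipeline,
    lifespan_summary,
    logrank_test,
    simulate_survival,
)
from nemaquant.exceptions import InvalidConfigError


def _rec(day, status, group="g", i=[0]):
    i[0] += 1
    return SurvivalRecord(worm_id=f"w{i[0]}", group=group, event_day=day,
                          status=status)


class TestKMEstimate:
    def test_all_dead_same_day_steps_to_zero(self):
        recs = [_rec(20.0, "dead") for _ in range(10)]
        curve = km_estimate(recs)
        assert list(curve.times) == [20.0]
        assert curve.survival[0] == 0.0

    def test_hand_product_limit_fixture(self):
        """Deaths at days 2 and 4, one censoring at day 2, n = 3."""
        recs = [_rec(2.0, "dead"), _rec(2.0, "censored"), _rec(4.0, "dead")]
        curve = km_estimate(recs)
        assert curve.survival_at(2.0) == pytest.approx(2 / 3)
        assert curve.survival_at(4.0) == pytest.approx(0.0)
        # matches an independent hand product-limit computation
        hand = oracles.km_hand_product_limit([2, 2, 4], [True, False, True])
        for t, s in hand:
            assert curve.survival_at(t) == pytest.approx(s)

    def test_all_censored_keeps_survival_at_one(self):
        recs = [_rec(d, "censored") for d in (2.0, 4.0, 6.0)]
        curve = km_estimate(recs)
        assert np.all(curve.survival == 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidConfigError):
            km_estimate([])

    @settings(derandomize=True, max_examples=25)
    @given(days=st.lists(st.integers(1, 15).map(lambda d: 2.0 * d),
                         min_size=1, max_size=30))
    def test_equals_empirical_survival_without_censoring(self, days):
        recs = [_rec(d, "dead") for d in days]
        curve = km_estimate(recs)
        days_arr = np.array(days)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(days_arr > t))


class TestLifespanSummary:
    def test_degenerate_cohort(self):
        curve = km_estimate([_rec(20.0, "dead") for _ in range(5)])
        summary = lifespan_summary(curve)
        assert summary.mean_lifespan == pytest.approx(20.0)
        assert summary.day75 == 20.0

    def test_two_step_hand_computation(self):
        curve = KMCurve(times=np.array([10.0, 30.0]),
                        survival=np.array([0.5, 0.0]),
                        at_risk=np.array([2, 1]), deaths=np.array([1, 1]),
                        censored=np.array([0, 0]))
        summary = lifespan_summary(curve)
        assert summary.mean_lifespan == pytest.approx(20.0)  # 10*1 + 20*0.5
        assert summary.day75 == 30.0

    def test_day75_undefined_when_survival_stays_high(self):
        curve = KMCurve(times=np.array([10.0]), survival=np.array([0.8]),
                        at_risk=np.array([5]), deaths=np.array([1]),
                        censored=np.array([0]))
        summary = lifespan_summary(curve)
        assert not summary.day75_defined
        assert summary.day75 is None

    def test_restricted_mean_close_to_weibull_truncated_mean(self):
        """Uncensored Weibull cohorts: RMST ~ the distribution's mean."""
        means = []
        for seed in range(30):
            cfg = SurvivalSimConfig(groups={"g": (4.0, 20.0)}, n_worms=105,
                                    censor_prob=0.0, seed=seed)
            recs, _ = simulate_survival(cfg)
            means.append(lifespan_summary(km_estimate(recs)).mean_lifespan)
        # Weibull(4, 20) mean = 20*Gamma(1.25) ~ 18.13; grid rounding up
        # adds about half an observation interval
        from scipy.special import gamma
        expected = 20.0 * gamma(1.25) + 1.0
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - expected) < 4 * se + 0.2


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        recs = [_rec(d, "dead") for d in (2.0, 4.0, 6.0)]
        res = logrank_test(recs, list(recs))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_worm_example_matches_oe_oracle(self):
        a = [_rec(d, s, "a") for d, s in
             [(2.0, "dead"), (4.0, "dead"), (6.0, "censored")]]
        b = [_rec(d, s, "b") for d, s in
             [(4.0, "dead"), (8.0, "dead"), (10.0, "dead")]]
        res = logrank_test(a, b)
        chi2 = oracles.logrank_chi2([2, 4, 6], [1, 1, 0], [4, 8, 10],
                                    [1, 1, 1])
        assert res.chi_square == pytest.approx(chi2, rel=1e-6)

    def test_symmetric_under_group_exchange(self):
        a = [_rec(d, "dead", "a") for d in (2.0, 6.0, 8.0)]
        b = [_rec(d, "dead", "b") for d in (4.0, 10.0, 12.0)]
        assert logrank_test(a, b).chi_square == pytest.approx(
            logrank_test(b, a).chi_square)

    def test_bonferroni_monotone_and_capped(self):
        a = [_rec(d, "dead", "a") for d in (2.0, 4.0)]
        b = [_rec(d, "dead", "b") for d in (2.0, 6.0)]
        r1 = logrank_test(a, b, n_comparisons=1)
        r5 = logrank_test(a, b, n_comparisons=5)
        assert r1.p_bonferroni == pytest.approx(r1.p)
        assert r5.p_bonferroni >= r5.p
        assert r5.p_bonferroni <= 1.0

    def test_group_without_events_warns_not_raises(self):
        a = [_rec(d, "dead", "a") for d in (2.0, 4.0)]
        b = [_rec(d, "censored", "b") for d in (2.0, 6.0)]
        with pytest.warns(UserWarning):
            logrank_test(a, b)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        p = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(oracles.fisher_p_enumeration(10, 0, 0, 10),
                                  rel=1e-9)

    def test_empty_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    @settings(derandomize=True, max_examples=60)
    @given(a=st.integers(0, 15), b=st.integers(0, 15),
           c=st.integers(0, 15), d=st.integers(0, 15))
    def test_agrees_with_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
            oracles.fisher_p_enumeration(a, b, c, d), rel=1e-9, abs=1e-12)


class TestLifespanPipeline:
    def test_single_group_summaries_only(self):
        recs = [_rec(d, "dead", "only") for d in (2.0, 4.0, 6.0)]
        out = lifespan_pipeline(recs)
        assert list(out["summaries"]) == ["only"]
        assert out["comparisons"] == []

    def test_control_comparisons_and_bonferroni_count(self):
        recs = []
        for g, offset in (("n2", 0.0), ("m1", 2.0), ("m2", 4.0)):
            recs += [_rec(d + offset, "dead", g) for d in (10.0, 12.0, 14.0)]
        out = lifespan_pipeline(recs, control="n2")
        assert len(out["comparisons"]) == 2
        for r in out["comparisons"]:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p * 2))

    def test_fully_censored_group_flagged(self):
        recs = [_rec(d, "censored", "c") for d in (2.0, 4.0)]
        with pytest.warns(UserWarning, match="fully censored"):
            out = lifespan_pipeline(recs)
        assert out["summaries"]["c"].n_censored == 2

    def test_off_grid_day_warns(self):
        recs = [_rec(3.0, "dead"), _rec(4.0, "dead")]
        with pytest.warns(UserWarning, match="off the"):
            lifespan_pipeline(recs)
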