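"""Survival layer oracles: KM, log-rank, Cox, risk groups, concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from mdsmc import survival as surv


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        c = surv.kaplan_meier([3, 5, 8], [0, 0, 0])
        assert (c.S == 1.0).all()

    def test_all_events_closed_form(self):
        c = surv.kaplan_meier([1, 2, 3], [1, 1, 1])
        assert np.allclose(c.S, [2 / 3, 1 / 3, 0.0])

    def test_mixed_censoring_matches_hand_table(self):
        """times 1,2+,3,4+,5 with events at 1,3,5:
        S(1)=4/5; S(3)=4/5*2/3=8/15; S(5)=0."""
        c = surv.kaplan_meier([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
        s_at = dict(zip(c.times, c.S))
        assert s_at[1.0] == pytest.approx(4 / 5)
        assert s_at[3.0] == pytest.approx(8 / 15)
        assert s_at[5.0] == pytest.approx(0.0)

    def test_curve_invariants(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 200)
        e = rng.integers(0, 2, 200)
        c = surv.kaplan_meier(t, e)
        c.validate()
        assert c.survival_at(0.0) == 1.0

    def test_merged_identical_groups_equal_curve(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 0, 1, 1])
        single = surv.kaplan_meier(t, e)
        merged = surv.kaplan_meier(np.r_[t, t], np.r_[e, e])
        assert np.allclose(
            single.survival_at(np.linspace(0, 8, 20)),
            merged.survival_at(np.linspace(0, 8, 20)),
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            surv.kaplan_meier([], [])


def hand_logrank(t1, e1, t2, e2):
    """Two-group log-rank oracle: sum over event times of O-E and
    hypergeometric variance, statistic (O-E)^2/V."""
    times = sorted(set(np.r_[t1, t2][np.r_[e1, e2] == 1]))
    O_E = V = 0.0
    for t in times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        O_E += d1 - d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return O_E**2 / V


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        stat, p = surv.logrank_pairwise(t + t, e + e, [0] * 4 + [1] * 4)
        assert stat.loc[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert p.loc[0, 1] == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        t1 = np.array([1.0, 3.0, 5.0, 7.0])
        e1 = np.array([1, 1, 0, 1])
        t2 = np.array([2.0, 4.0, 6.0, 8.0])
        e2 = np.array([1, 1, 1, 0])
        stat, p = surv.logrank_pairwise(
            np.r_[t1, t2], np.r_[e1, e2], [0] * 4 + [1] * 4
        )
        expected = hand_logrank(t1, e1, t2, e2)
        assert stat.loc[0, 1] == pytest.approx(expected, rel=1e-9)
        assert p.loc[0, 1] == pytest.approx(chi2.sf(expected, df=1), rel=1e-9)

    def test_p_invariant_to_label_swap(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        g = rng.integers(0, 2, 60)
        _, p1 = surv.logrank_pairwise(t, e, g)
        _, p2 = surv.logrank_pairwise(t, e, 1 - g)
        assert p1.loc[0, 1] == pytest.approx(p2.loc[1, 0])


class TestCox:
    def test_null_covariate_small_coefficient(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.normal(size=n)
        t = rng.exponential(10, n)
        e = np.ones(n, dtype=int)
        out = surv.cox_ph(t, e, pd.DataFrame({"x": x}))
        assert abs(out.loc["x", "coef"]) < 0.1

    def test_recovers_log_hr_two(self):
        """Two-group exponential with hazard ratio 2: beta within 0.1 of ln 2."""
        rng = np.random.default_rng(12)
        n = 2000
        g = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / np.exp(np.log(2) * g), n)
        e = np.ones(n, dtype=int)
        out = surv.cox_ph(t, e, pd.DataFrame({"g": g.astype(float)}))
        assert out.loc["g", "coef"] == pytest.approx(np.log(2), abs=0.1)
        assert out.attrs["concordance"] > 0.5

    def test_rescaling_covariate_rescales_coefficient(self):
        rng = np.random.default_rng(13)
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x), n)
        e = np.ones(n, dtype=int)
        b1 = surv.cox_ph(t, e, pd.DataFrame({"x": x})).loc["x", "coef"]
        b10 = surv.cox_ph(t, e, pd.DataFrame({"x": 10 * x})).loc["x", "coef"]
        assert b10 == pytest.approx(b1 / 10, rel=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            surv.cox_ph([1, 2, 3], [1, 1, 1], pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


def _weibull_curves(scales, n_per=500, seed=0):
    rng = np.random.default_rng(seed)
    curves, data = {}, {}
    for i, s in enumerate(scales):
        t = s * rng.weibull(1.2, n_per)
        e = np.ones(n_per, dtype=int)
        name = f"MC{i + 1}"
        curves[name] = surv.kaplan_meier(t, e)
        data[name] = (t, e)
    return curves, data


class TestRiskGroups:
    def test_identical_curves_single_group(self):
        t = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        e = np.ones(5, dtype=int)
        c = surv.kaplan_meier(t, e)
        grouping = surv.aggregate_risk_groups({"MC1": c, "MC2": c, "MC3": c})
        assert grouping.n_groups == 1

    def test_recovers_three_planted_tiers(self):
        """Six MCs drawn from three Weibull scales collapse to 3 groups."""
        curves, data = _weibull_curves([60, 60, 25, 25, 8, 8], seed=14)
        grouping = surv.aggregate_risk_groups(curves, survival_data=data)
        assert grouping.n_groups == 3
        a = grouping.assignment
        assert a["MC1"] == a["MC2"]
        assert a["MC3"] == a["MC4"]
        assert a["MC5"] == a["MC6"]
        # ordered best-to-worst by median OS
        assert a["MC1"] < a["MC3"] < a["MC5"]

    def test_fixed_group_count_honored(self):
        curves, data = _weibull_curves([70, 50, 30, 18, 9, 4], seed=15)
        cfg = surv.RiskGroupingConfig(n_groups_target=5)
        grouping = surv.aggregate_risk_groups(curves, cfg, survival_data=data)
        assert grouping.n_groups == 5

    def test_group_count_monotone_in_floor(self):
        curves, data = _weibull_curves([60, 60, 25, 25, 8, 8], seed=16)
        counts = []
        for floor in (0.1, 0.25, 0.5):
            cfg = surv.RiskGroupingConfig(survival_floor=floor)
            counts.append(
                surv.aggregate_risk_groups(curves, cfg, survival_data=data).n_groups
            )
        assert counts[0] >= counts[1] >= counts[2] or len(set(counts)) == 1


def brute_force_c(times, events, scores):
    """Usable-pair oracle: pair (i,j) usable iff the earlier time is an
    event; concordant when the earlier death has the higher risk score."""
    conc = ties = usable = 0
    for i, j in itertools.combinations(range(len(times)), 2):
        ti, tj = times[i], times[j]
        if ti == tj and events[i] == events[j] == 1:
            usable += 1
            ties += scores[i] == scores[j]
            continue
        first, second = (i, j) if ti < tj else (j, i)
        if events[first] != 1:
            continue
        usable += 1
        if scores[first] > scores[second]:
            conc += 1
        elif scores[first] == scores[second]:
            ties += 1
    return (conc + 0.5 * ties) / usable


class TestConcordance:
    def test_perfect_ordering_scores_one(self):
        t = np.array([5.0, 3.0, 9.0, 1.0])
        scores = 1.0 / t
        assert surv.harrell_c(t, np.ones(4, dtype=int), scores) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(10, 1000)
        s = rng.normal(size=1000)
        c = surv.harrell_c(t, np.ones(1000, dtype=int), s)
        assert abs(c - 0.5) < 0.05

    def test_matches_brute_force_on_censored_fixture(self):
        t = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 7.0])
        e = np.array([1, 0, 1, 1, 0, 1, 0])
        s = np.array([0.9, 0.3, 0.5, 0.7, 0.2, 0.4, 0.1])
        assert surv.harrell_c(t, e, s) == pytest.approx(brute_force_c(t, e, s))

    def test_bootstrap_difference_brackets_zero_for_identical_models(self):
        rng = np.random.default_rng(18)
        t = rng.exponential(10, 300)
        e = rng.integers(0, 2, 300)
        s = rng.normal(size=300)
        delta, (lo, hi) = surv.bootstrap_c_difference(t, e, s, s, n_boot=50, seed=1)
        assert delta == 0.0 and lo == 0.0 and hi == 0.0

    def test_bootstrap_detects_better_model(self):
        rng = np.random.default_rng(19)
        n = 400
        t = rng.exponential(10, n)
        informative = -t + rng.normal(scale=2.0, size=n)
        noise = rng.normal(size=n)
        delta, (lo, hi) = surv.bootstrap_c_difference(
            t, np.ones(n, dtype=int), informative, noise, n_boot=200, seed=2
        )
        assert delta > 0 and lo > 0


class TestResponseLogistic:
    def test_null_association_cis_cover_one(self):
        rng = np.random.default_rng(20)
        n = 2000
        clusters = rng.integers(0, 4, n)
        y = rng.integers(0, 2, n)
        out = surv.response_logistic(y, clusters)
        terms = [ix for ix in out.index if ix.startswith("MC_")]
        cover = [(out.loc[t, "OR_lower"] <= 1 <= out.loc[t, "OR_upper"]) for t in terms]
        assert all(cover)

    def test_recovers_planted_odds_ratio(self):
        rng = np.random.default_rng(1)
        n = 2000
        clusters = rng.integers(0, 3, n)
        base_logit = -1.0
        logit = base_logit + np.where(clusters == 2, np.log(2.0), 0.0)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        out = surv.response_logistic(y, clusters, reference="0")
        assert out.loc["MC_2", "OR_lower"] <= 2.0 <= out.loc["MC_2", "OR_upper"]

    def test_degenerate_response_rejected(self):
        with pytest.raises(ValueError):
            surv.response_logistic(np.zeros(10, dtype=int), np.arange(10) % 2)
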