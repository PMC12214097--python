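"""ROC/AUC, Youden cutoffs, regression models, survival curves, group tests."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from subacrodyn import (
    GenerativeParams,
    binormal_auc,
    compare_groups,
    empirical_auc,
    fit_cox,
    fit_logistic_adjusted,
    km_logrank,
    simulate_cohort,
    youden_cutoff,
)


def brute_force_auc(scores, labels, orientation="higher_is_positive"):
    """Pairwise concordance count over all positive x negative pairs."""
    s = np.asarray(scores, float)
    if orientation == "lower_is_positive":
        s = -s
    pos, neg = s[np.asarray(labels, bool)], s[~np.asarray(labels, bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        r = empirical_auc([1, 2, 3, 4], [False, False, True, True])
        assert r.auc == 1.0 and r.n_pos == 2 and r.n_neg == 2

    def test_pure_ties(self):
        r = empirical_auc([5.0] * 6, [True, False] * 3)
        assert r.auc == 0.5

    def test_half_concordant_hand_instance(self):
        r = empirical_auc([3, 1, 2, 4], [False, True, False, True])
        assert r.auc == 0.5  # 2 concordant of 4 pairs

    @pytest.mark.parametrize("n,seed", [(10, 0), (50, 1), (200, 2), (75, 3)])
    def test_matches_pairwise_bruteforce(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        for orientation in ("higher_is_positive", "lower_is_positive"):
            r = empirical_auc(scores, labels, orientation)
            assert r.auc == pytest.approx(
                brute_force_auc(scores, labels, orientation), abs=1e-12
            )
            assert r.ci_low <= r.auc <= r.ci_high

    def test_orientations_are_complementary(self):
        rng = np.random.default_rng(7)
        scores = np.round(rng.normal(size=40), 1)
        labels = rng.random(40) < 0.5
        hi = empirical_auc(scores, labels, "higher_is_positive").auc
        lo = empirical_auc(scores, labels, "lower_is_positive").auc
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_converges_to_binormal_closed_form(self):
        rng = np.random.default_rng(11)
        n = 100_000
        scores = np.concatenate(
            [rng.normal(0.21, 0.15, n), rng.normal(0.35, 0.18, n)]
        )
        labels = np.repeat([False, True], n)
        emp = empirical_auc(scores, labels).auc
        assert abs(emp - binormal_auc(0.35, 0.18, 0.21, 0.15)) < 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([1, 2, 3], [True, True, True])


def youden_oracle(scores, labels, orientation="higher_is_positive"):
    """Exhaustive scan over midpoint thresholds with the stated tie rule."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(scores)
    cands = [-np.inf, *((uniq[:-1] + uniq[1:]) / 2), np.inf]
    best = None
    for thr in cands:
        if orientation == "higher_is_positive":
            sens = np.mean(scores[labels] > thr)
            spec = np.mean(scores[~labels] <= thr)
        else:
            sens = np.mean(scores[labels] < thr)
            spec = np.mean(scores[~labels] >= thr)
        j = sens + spec - 1
        key = (j, sens, -thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec, j)
    return best[1:]


class TestYoudenCutoff:
    def test_perfect_separation_midpoint(self):
        r = youden_cutoff([0.1, 0.2, 0.6, 0.9], [False, False, True, True])
        assert r.youden_j == 1.0
        assert r.threshold == pytest.approx(0.4)  # midpoint of closest cross-group pair
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=20), 1)
        labels = rng.random(20) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        for orientation in ("higher_is_positive", "lower_is_positive"):
            r = youden_cutoff(scores, labels, orientation)
            thr, sens, spec, j = youden_oracle(scores, labels, orientation)
            assert r.youden_j == pytest.approx(j, abs=1e-12)
            assert r.threshold == pytest.approx(thr)
            assert (r.sensitivity, r.specificity) == pytest.approx((sens, spec))

    def test_j_dominates_every_observed_threshold(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        r = youden_cutoff(scores, labels)
        for thr in scores:
            sens = np.mean(scores[labels] > thr)
            spec = np.mean(scores[~labels] <= thr)
            assert r.youden_j >= sens + spec - 1 - 1e-12

    def test_tie_rule_is_deterministic(self):
        # labels independent of scores: many thresholds tie at J = 0
        scores = np.arange(8.0)
        labels = np.array([True, False] * 4)
        a = youden_cutoff(scores, labels)
        b = youden_cutoff(list(scores), list(labels))
        assert a == b
        thr, sens, spec, j = youden_oracle(scores, labels)
        assert a.threshold == pytest.approx(thr) and a.sensitivity == sens


class TestBinormalAuc:
    def test_equal_means_is_half(self):
        assert binormal_auc(0.3, 0.2, 0.3, 0.1) == pytest.approx(0.5)

    def test_antisymmetry(self):
        a = binormal_auc(0.35, 0.18, 0.21, 0.15)
        b = binormal_auc(0.21, 0.15, 0.35, 0.18)
        assert a + b == pytest.approx(1.0)

    def test_numeric_value(self):
        assert binormal_auc(0.35, 0.18, 0.21, 0.15) == pytest.approx(0.7249, abs=5e-4)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            binormal_auc(0.3, 0.0, 0.2, 0.1)


class TestLogistic:
    def test_null_predictor_ci_contains_one(self):
        df = simulate_cohort(GenerativeParams(n=500, or_per_cm=1.0, seed=21))
        r = fit_logistic_adjusted(df, "early_success", "mvahd_fab_cm")
        assert r.odds_ratio.ci_low < 1.0 < r.odds_ratio.ci_high

    def test_recovers_known_odds_ratio(self):
        df = simulate_cohort(GenerativeParams(n=2000, or_per_cm=2.0, seed=0))
        r = fit_logistic_adjusted(df, "early_success", "mvahd_fab_cm")
        assert 1.6 <= r.odds_ratio.estimate <= 2.5
        assert r.odds_ratio.ci_low <= r.odds_ratio.estimate <= r.odds_ratio.ci_high

    def test_row_duplication_leaves_point_estimate(self):
        df = simulate_cohort(GenerativeParams(n=300, or_per_cm=1.8, seed=4))
        a = fit_logistic_adjusted(df, "early_success", "mvahd_fab_cm")
        b = fit_logistic_adjusted(
            pd.concat([df, df], ignore_index=True), "early_success", "mvahd_fab_cm"
        )
        assert b.odds_ratio.estimate == pytest.approx(a.odds_ratio.estimate, rel=1e-6)

    def test_constant_outcome_rejected(self):
        df = simulate_cohort(GenerativeParams(n=50, seed=1))
        df["early_success"] = 1
        with pytest.raises(ValueError, match="binary"):
            fit_logistic_adjusted(df, "early_success", "mvahd_fab_cm")


class TestCox:
    def test_null_predictor_ci_contains_one(self):
        df = simulate_cohort(GenerativeParams(n=500, hr_per_cm=1.0, seed=13))
        r = fit_cox(df, "time_days", "event", "mvahd_fab_cm")
        assert r.hazard_ratio.ci_low < 1.0 < r.hazard_ratio.ci_high

    def test_recovers_known_hazard_ratio(self):
        df = simulate_cohort(
            GenerativeParams(n=2000, hr_per_cm=2.0, censoring_fraction=0.2, seed=0)
        )
        r = fit_cox(df, "time_days", "event", "mvahd_fab_cm")
        assert 1.6 <= r.hazard_ratio.estimate <= 2.5

    def test_time_scale_invariance(self):
        df = simulate_cohort(GenerativeParams(n=400, hr_per_cm=1.7, seed=6))
        a = fit_cox(df, "time_days", "event", "mvahd_fab_cm")
        scaled = df.copy()
        scaled["time_days"] = scaled["time_days"] * 7.3
        b = fit_cox(scaled, "time_days", "event", "mvahd_fab_cm")
        assert b.hazard_ratio.estimate == pytest.approx(
            a.hazard_ratio.estimate, rel=1e-6
        )

    def test_no_events_rejected(self):
        df = simulate_cohort(GenerativeParams(n=50, seed=2))
        df["event"] = 0
        with pytest.raises(ValueError, match="event"):
            fit_cox(df, "time_days", "event", "mvahd_fab_cm")


def logrank_oracle(times, events, groups):
    """Hand bookkeeping: 2x2 table cascade over pooled event times."""
    times, events, groups = map(np.asarray, (times, events, groups))
    names = sorted(set(groups))
    o1 = e1 = v = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == names[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == names[0])).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


class TestSurvival:
    def test_identical_groups_chi_square_zero(self):
        times = np.array([3, 5, 8, 12, 20, 30.0] * 2)
        events = np.ones(12, int)
        groups = np.repeat(["a", "b"], 6)
        _, lr = km_logrank(times, events, groups)
        assert lr.chi_square == pytest.approx(0.0, abs=1e-10)
        assert lr.p_value == pytest.approx(1.0, abs=1e-10)

    def test_km_without_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(3)
        times = np.concatenate([rng.exponential(100, 11), rng.exponential(60, 11)])
        events = np.ones(22, int)
        groups = np.repeat(["a", "b"], 11)
        curves, _ = km_logrank(times, events, groups)
        for g in ("a", "b"):
            tg = np.sort(times[groups == g])
            for t_obs, s_obs in zip(curves[g].times, curves[g].survival):
                assert s_obs == pytest.approx(np.mean(tg > t_obs), abs=1e-12)
            # restricted mean to the largest observed time = sample mean
            if tg.max() == times.max():
                assert curves[g].mean_time == pytest.approx(tg.mean(), rel=1e-3)

    def test_km_median_equals_sample_median_without_censoring(self):
        times = np.array([5, 9, 14, 22, 31, 44, 60, 75, 90, 120, 150.0])
        events = np.ones(11, int)
        curves, _ = km_logrank(
            np.concatenate([times, times + 1]),
            np.ones(22, int),
            np.repeat(["a", "b"], 11),
        )
        c = curves["a"]
        km_median = c.times[np.searchsorted(-c.survival, -0.5)]
        assert km_median == np.median(times)

    def test_twelve_subject_hand_cascade(self):
        times = np.array([3, 4, 5, 6, 8, 10, 12, 14, 15, 20, 25, 30.0])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1, 0, 1])
        groups = np.repeat(["a", "b"], 6)
        _, lr = km_logrank(times, events, groups)
        assert lr.chi_square == pytest.approx(
            logrank_oracle(times, events, groups), rel=1e-9
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3.0], [1, 1, 1], ["a", "a", "a"])


class TestCompareGroups:
    def test_identical_proportions_p_one(self):
        df = pd.DataFrame(
            {"group": ["a"] * 20 + ["b"] * 20, "flag": ([True] * 5 + [False] * 15) * 2}
        )
        r = compare_groups(df, "flag", "group")
        assert r.test == "chi_square"
        assert r.p_value == pytest.approx(1.0)

    def test_tenosynovitis_prevalence_contrast_significant(self):
        # 14/90 vs 33/90 affected shoulders
        df = pd.DataFrame(
            {
                "group": ["non_affected"] * 90 + ["affected"] * 90,
                "flag": [True] * 14 + [False] * 76 + [True] * 33 + [False] * 57,
            }
        )
        r = compare_groups(df, "flag", "group")
        assert r.test == "chi_square" and r.p_value < 0.05

    def test_fisher_on_zero_cell_matches_hypergeometric_enumeration(self):
        # rows: groups (a: 0/10, b: 5/10)
        df = pd.DataFrame(
            {
                "group": ["a"] * 10 + ["b"] * 10,
                "flag": [False] * 10 + [True] * 5 + [False] * 5,
            }
        )
        r = compare_groups(df, "flag", "group")
        assert r.test == "fisher_exact"
        # enumeration oracle: P(X = k) summed over outcomes no more likely
        # than the observed table; X ~ Hypergeom(N=20, K=5 flagged, n=10 in a)
        rv = sps.hypergeom(20, 5, 10)
        p_obs = rv.pmf(0)
        expected = sum(
            rv.pmf(k) for k in range(0, 6) if rv.pmf(k) <= p_obs * (1 + 1e-9)
        )
        assert r.p_value == pytest.approx(expected, rel=1e-9)

    def test_normal_data_gated_to_t_test(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], 40),
                "x": np.concatenate([rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)]),
            }
        )
        assert compare_groups(df, "x", "group").test == "t_test"

    def test_skewed_data_gated_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], 40),
                "x": np.concatenate(
                    [rng.lognormal(0, 1, 40), rng.lognormal(0.5, 1, 40)]
                ),
            }
        )
        assert compare_groups(df, "x", "group").test == "mann_whitney_u"

    def test_tiny_group_falls_back_with_warning(self):
        df = pd.DataFrame({"group": ["a", "a", "b", "b", "b"], "x": [1.0, 2, 3, 4, 5]})
        r = compare_groups(df, "x", "group")
        assert r.test == "mann_whitney_u" and r.warnings

    def test_paired_wilcoxon(self):
        rng = np.random.default_rng(5)
        before = rng.normal(6, 1, 30)
        df = pd.DataFrame({"before": before, "after": before - rng.normal(3, 0.5, 30)})
        r = compare_groups(df, ("before", "after"), paired=True)
        assert r.test == "wilcoxon_signed_rank" and r.p_value < 0.001
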