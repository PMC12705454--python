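"""Propensity matching, interaction models, survival and auxiliary tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctsnet.clinical import (
    chi2_posthoc,
    estimate_propensity,
    km_logrank,
    kruskal_dunn,
    levene_test,
    logistic_interaction,
    nn_match,
    nri_bootstrap,
    percent,
    roc_auc,
    standardized_mean_differences,
    table_one,
)


def confounded_cohort(n=2000, seed=0):
    # moderate severity confounding, ~1/3 treated: the overlap regime in
    # which 1:1 caliper matching is the appropriate design
    rng = np.random.default_rng(seed)
    sofa = rng.normal(7, 2.5, n)
    shock = (rng.random(n) < 0.3).astype(int)
    age = rng.normal(60, 14, n)
    lin = 0.4 * (sofa - 7) / 2.5 + 0.4 * shock + 0.05 * (age - 60) / 14 - 0.8
    treated = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
    return pd.DataFrame(
        {"sofa": sofa, "shock": shock, "age": age, "treated": treated},
        index=[f"p{i}" for i in range(n)],
    )


class TestPropensity:
    def test_null_covariates_recover_prevalence(self):
        rng = np.random.default_rng(1)
        n = 5000
        clin = pd.DataFrame(
            {
                "sofa": rng.normal(7, 2, n),
                "age": rng.normal(60, 10, n),
                "treated": (rng.random(n) < 0.4).astype(int),
            }
        )
        scores = estimate_propensity(clin, ["sofa", "age"])
        assert scores.mean() == pytest.approx(0.4, abs=0.02)
        assert scores.std() < 0.03

    def test_monotone_in_a_strong_confounder(self):
        clin = confounded_cohort()
        scores = estimate_propensity(clin, ["sofa", "shock", "age"])
        order = clin["sofa"].sort_values().index
        lo = scores[order[:500]].mean()
        hi = scores[order[-500:]].mean()
        assert hi > lo + 0.1

    def test_duplicated_rows_get_identical_scores(self):
        clin = confounded_cohort(n=200, seed=3)
        doubled = pd.concat([clin, clin.set_axis([f"d{i}" for i in
                                                  range(200)])])
        scores = estimate_propensity(doubled, ["sofa", "shock", "age"])
        assert np.allclose(scores.iloc[:200].to_numpy(),
                           scores.iloc[200:].to_numpy())


class TestMatching:
    def test_nearest_neighbor_picks_closest_control(self):
        scores = pd.Series({"t": 0.6, "c1": 0.55, "c2": 0.9})
        treated = pd.Series({"t": 1, "c1": 0, "c2": 0})
        m = nn_match(scores, treated, caliper_sd=100.0)
        assert list(m.pairs[["treated_id", "control_id"]].iloc[0]) == ["t", "c1"]

    def test_zero_caliper_keeps_only_exact_pairs(self):
        scores = pd.Series({"t1": 0.4, "t2": 0.7, "c1": 0.4, "c2": 0.71})
        treated = pd.Series({"t1": 1, "t2": 1, "c1": 0, "c2": 0})
        m = nn_match(scores, treated, caliper=0.0)
        assert len(m.pairs) == 1
        assert m.n_dropped_treated == 1
        assert list(m.pairs[["treated_id", "control_id"]].iloc[0]) == ["t1", "c1"]

    def test_matching_balances_confounded_cohort(self):
        clin = confounded_cohort()
        covars = ["sofa", "shock", "age"]
        scores = estimate_propensity(clin, covars)
        m = nn_match(scores, clin["treated"], clinical=clin, covariates=covars)
        assert (m.smd_pre > 0.1).any()
        assert (m.smd_post < 0.1).all()

    def test_pairs_never_share_an_arm(self):
        clin = confounded_cohort(n=400, seed=5)
        scores = estimate_propensity(clin, ["sofa", "shock", "age"])
        m = nn_match(scores, clin["treated"])
        assert clin.loc[m.pairs["treated_id"], "treated"].eq(1).all()
        assert clin.loc[m.pairs["control_id"], "treated"].eq(0).all()
        assert m.pairs["control_id"].is_unique
        assert m.pairs["treated_id"].is_unique


class TestLogisticInteraction:
    def test_single_factor_or_equals_cross_product_ratio(self):
        # saturated 2x2: OR == ad/bc to numerical precision
        rows = (
            [("a", 1, 1)] * 30 + [("a", 1, 0)] * 70
            + [("a", 0, 1)] * 20 + [("a", 0, 0)] * 80
        )
        clin = pd.DataFrame(rows, columns=["cts", "treated", "event"])
        fit = logistic_interaction(clin)
        or_treated = fit.table.loc["treated", "odds_ratio"]
        assert or_treated == pytest.approx((30 * 80) / (70 * 20), abs=1e-8)

    def test_planted_interaction_recovered_within_ci(self):
        rng = np.random.default_rng(4)
        n = 2000
        cts = rng.choice(["1", "2"], n)
        treated = rng.integers(0, 2, n)
        logit = -1.0 + 0.5 * treated + 0.3 * (cts == "2") + 0.8 * treated * (
            cts == "2"
        )
        event = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        clin = pd.DataFrame({"cts": cts, "treated": treated, "event": event})
        fit = logistic_interaction(clin)
        term = 'treated:C(cts)[T.2]'
        lo, hi = fit.table.loc[term, ["ci_low", "ci_high"]]
        assert lo <= np.exp(0.8) <= hi

    def test_constant_outcome_errors(self):
        clin = pd.DataFrame(
            {"cts": ["1", "2"] * 10, "treated": [0, 1] * 10, "event": 0}
        )
        with pytest.raises(ValueError, match="constant"):
            logistic_interaction(clin)


class TestKMLogrank:
    def test_no_censoring_steps_of_one_over_n(self):
        time = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = pd.Series([1] * 6)
        group = pd.Series(["a"] * 3 + ["b"] * 3)
        res = km_logrank(time, event, group)
        sf = res.curves["a"].iloc[:, 0].to_numpy()
        assert np.allclose(np.diff(sf), -1 / 3)

    def test_identical_groups_statistic_zero(self):
        time = pd.Series([2.0, 3.0, 5.0, 2.0, 3.0, 5.0])
        event = pd.Series([1, 0, 1, 1, 0, 1])
        group = pd.Series(["a"] * 3 + ["b"] * 3)
        res = km_logrank(time, event, group)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_matches_hand_logrank_table(self):
        # 6 patients, no censoring; observed-vs-expected computed by hand
        time = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = pd.Series([1, 1, 1, 1, 1, 1])
        group = pd.Series(["a", "a", "a", "b", "b", "b"])
        # at t=1..6, at-risk (a, b) and deaths alternate; hand computation:
        # E_a = 3/6 + 2/5 + 1/4 + 0 + 0 + 0 = 1.15 ; O_a = 3
        # V = sum of n_a n_b (N - 1... (hypergeometric variances):
        # t1: (3*3)/(6^2) *1*(6-1)/(6-1)=0.25 ; t2: (2*3)/25=0.24 ;
        # t3: (1*3)/16=0.1875 ; later terms 0
        o_minus_e = 3 - (3 / 6 + 2 / 5 + 1 / 4)
        v = (3 * 3) / 36 + (2 * 3) / 25 + (1 * 3) / 16
        expected = o_minus_e**2 / v
        res = km_logrank(time, event, group)
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_empty_group_errors(self):
        time = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank(time, pd.Series([1, 1]), pd.Series(["a", "a"]))


class TestChi2Posthoc:
    def test_identical_proportions_statistic_zero(self):
        res = chi2_posthoc(pd.DataFrame([[10, 20, 40], [5, 10, 20]]))
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_matches_hand_formula(self):
        tab = np.array([[10, 20], [20, 10]])
        total = tab.sum()
        expected_counts = np.outer(tab.sum(1), tab.sum(0)) / total
        hand = ((tab - expected_counts) ** 2 / expected_counts).sum()
        res = chi2_posthoc(pd.DataFrame(tab))
        assert res["statistic"] == pytest.approx(hand, abs=1e-10)

    def test_three_columns_bonferroni_times_three(self):
        tab = pd.DataFrame([[30, 10, 20], [10, 30, 20]],
                           columns=["c1", "c2", "c3"])
        res = chi2_posthoc(tab)
        assert len(res["pairwise"]) == 3
        for pair in res["pairwise"].values():
            assert pair["p_adj"] == pytest.approx(
                min(pair["p_raw"] * 3, 1.0), abs=1e-12
            )


class TestKruskalDunn:
    def test_identical_groups_all_adjusted_p_one(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["a", "b", "c"], 4)
        res = kruskal_dunn(vals, groups)
        assert all(p["p_adj"] == 1.0 for p in res["pairwise"].values())

    def test_z_matches_hand_rank_mean_formula(self):
        vals = np.array([1.0, 3, 5, 2, 4, 9, 8, 7, 6])
        groups = np.repeat(["a", "b", "c"], 3)
        res = kruskal_dunn(vals, groups)
        ranks = stats.rankdata(vals)
        n = 9
        se = np.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 3))
        z_ab = (ranks[:3].mean() - ranks[3:6].mean()) / se
        assert res["pairwise"][("a", "b")]["z"] == pytest.approx(z_ab,
                                                                 abs=1e-10)

    def test_shift_alternative_power(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 40)
            b = rng.normal(0, 1, 40)
            c = rng.normal(1.0, 1, 40)
            res = kruskal_dunn(
                np.concatenate([a, b, c]), np.repeat(["a", "b", "c"], 40)
            )
            hits += res["pairwise"][("a", "c")]["p_adj"] < 0.05
        assert hits / 100 > 0.8

    def test_two_groups_error(self):
        with pytest.raises(ValueError, match="3 groups"):
            kruskal_dunn(np.arange(6.0), np.repeat(["a", "b"], 3))


class TestROCAndNRI:
    def test_auc_extremes_and_pair_counting(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.5] * 4, [0, 0, 1, 1]) == 0.5
        score = [0.2, 0.6, 0.4, 0.9, 0.4]
        outcome = [0, 1, 0, 1, 1]
        pos = [s for s, o in zip(score, outcome) if o]
        neg = [s for s, o in zip(score, outcome) if not o]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(score, outcome) == pytest.approx(
            wins / (len(pos) * len(neg)), abs=1e-12
        )

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        score = rng.random(50)
        outcome = rng.integers(0, 2, 50)
        assert roc_auc(score, outcome) == pytest.approx(
            roc_auc(np.exp(3 * score), outcome), abs=1e-12
        )

    def test_nri_zero_for_identical_risks(self):
        risk = np.array([0.2, 0.4, 0.6, 0.8])
        outcome = np.array([0, 0, 1, 1])
        res = nri_bootstrap(risk, risk, outcome, n_boot=50, seed=0)
        assert res["nri"] == 0.0

    def test_nri_maximal_for_perfect_reordering(self):
        outcome = np.array([1, 1, 0, 0])
        old = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.9, 0.9, 0.1, 0.1])
        res = nri_bootstrap(old, new, outcome, n_boot=50, seed=0)
        assert res["nri"] == 2.0

    def test_nri_matches_hand_tally_on_eight_patients(self):
        outcome = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        old = np.array([0.5, 0.4, 0.3, 0.6, 0.2, 0.5, 0.3, 0.2])
        new = np.array([0.7, 0.3, 0.3, 0.4, 0.3, 0.5, 0.1, 0.4])
        # events: up {0, 7}, down {1} -> (2 - 1)/4
        # non-events: down {3, 6}, up {4} -> (2 - 1)/4
        assert nri_bootstrap(old, new, outcome, n_boot=50, seed=0)[
            "nri"
        ] == pytest.approx(0.25 + 0.25, abs=1e-12)

    def test_nri_without_events_errors(self):
        with pytest.raises(ValueError, match="events"):
            nri_bootstrap([0.1], [0.2], [0], n_boot=10, seed=0)


class TestLevene:
    def test_identical_groups_statistic_zero(self):
        vals = np.tile([1.0, 2, 3, 4, 5], 2)
        stat, _ = levene_test(vals, np.repeat(["a", "b"], 5))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_inflated_variance_detected(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate([rng.normal(0, 1, 100), rng.normal(0, 3, 100)])
        _, p = levene_test(vals, np.repeat(["a", "b"], 100))
        assert p < 0.01


class TestTableOne:
    def test_printed_percentages_from_counts(self):
        assert percent(80, 497) == 16.1
        assert percent(61, 213) == 28.6
        assert percent(0, 100) == 0.0

    def test_half_up_rounding(self):
        assert percent(1, 8) == 12.5
        assert percent(25, 200) == 12.5
        assert percent(5, 400) == 1.3  # 1.25 rounds half-up

    def test_counts_and_percentages_per_group(self):
        clin = pd.DataFrame(
            {
                "shock": [1, 0, 1, 1, 0, 0],
                "age": [50.0, 60, 70, 55, 65, 75],
            },
            index=[f"p{i}" for i in range(6)],
        )
        labels = pd.Series(["1", "1", "1", "2", "2", "2"], index=clin.index)
        tab = table_one(clin, labels, categorical=["shock"],
                        continuous=["age"])
        assert tab.loc[("shock", "1"), "1_count"] == 2
        assert tab.loc[("shock", "1"), "1"] == percent(2, 3)
        assert tab.loc[("age", "median"), "2"] == 65.0

    def test_variable_specific_denominator(self):
        clin = pd.DataFrame({"shock": [1, 1, 0, 0]},
                            index=["a", "b", "c", "d"])
        labels = pd.Series(["1"] * 4, index=clin.index)
        tab = table_one(clin, labels, categorical=["shock"], continuous=[],
                        denominators={"shock": 8})
        assert tab.loc[("shock", "1"), "1"] == percent(2, 8)

    def test_zero_denominator_errors(self):
        clin = pd.DataFrame({"shock": [1]}, index=["a"])
        labels = pd.Series(["1"], index=clin.index)
        with pytest.raises(ValueError, match="denominator"):
            table_one(clin, labels, categorical=["shock"], continuous=[],
                      denominators={"shock": 0})

    def test_smd_zero_when_arms_identical(self):
        clin = pd.DataFrame(
            {"sofa": [5.0, 7.0, 5.0, 7.0], "treated": [1, 1, 0, 0]},
            index=list("abcd"),
        )
        smd = standardized_mean_differences(clin, ["sofa"])
        assert smd["sofa"] == 0.0
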