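import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dixonvol.stats import (
    BlandAltmanResult,
    bland_altman,
    rm_anova_two_way,
    roc_youden,
    spearman_rho,
    steatosis_label,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x**3).statistic == pytest.approx(1.0)
        assert spearman_rho(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # d = (-1, 1, -1, 1, 0): rho = 1 - 6*4 / (5*(25-1)) = 0.8
        res = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.statistic == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_methods(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_difference == 0.0
        assert r.loa_lower == r.loa_upper == 0.0

    def test_hand_computation(self):
        r = bland_altman([2.0, 4.0], [1.0, 1.0])  # d = (1, 3)
        assert r.mean_difference == pytest.approx(2.0)
        assert r.sd_diff == pytest.approx(math.sqrt(2))
        assert r.loa_lower == pytest.approx(2 - 1.96 * math.sqrt(2))
        assert r.loa_upper == pytest.approx(2 + 1.96 * math.sqrt(2))

    def test_limits_symmetric_and_antisymmetric_on_swap(self, rng):
        a = rng.normal(10, 3, 30)
        b = rng.normal(8, 3, 30)
        r = bland_altman(a, b)
        assert r.loa_upper - r.mean_difference == pytest.approx(
            r.mean_difference - r.loa_lower
        )
        s = bland_altman(b, a)
        assert s.mean_difference == pytest.approx(-r.mean_difference)
        assert s.loa_lower == pytest.approx(-r.loa_upper)
        assert s.loa_upper == pytest.approx(-r.loa_lower)

    def test_upper_limit_from_md_and_lower(self):
        # symmetric-limit identity: upper = 2*MD - lower
        r = BlandAltmanResult.from_md_and_lower(2.07, -2.93)
        assert round(r.loa_upper, 1) == 7.1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestRocYouden:
    def test_perfect_separation(self):
        r = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.youden_j == 1.0
        assert 3 < r.youden_threshold < 10

    def test_exhaustive_small_example(self):
        r = roc_youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.youden_threshold == pytest.approx(2.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([1, 2, 3], [1, 1, 1])

    def test_auc_equals_normalized_u_statistic(self, rng):
        """Trapezoidal AUC == Mann-Whitney U / (n_pos * n_neg), ties included."""
        from scipy.stats import mannwhitneyu

        for trial in range(50):
            n_pos = rng.integers(3, 20)
            n_neg = rng.integers(3, 20)
            pos = rng.normal(1.0, 1.0, n_pos)
            neg = rng.normal(0.0, 1.0, n_neg)
            if trial % 3 == 0:  # inject ties
                pos = np.round(pos)
                neg = np.round(neg)
            scores = np.concatenate([pos, neg])
            labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
            r = roc_youden(scores, labels)
            u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert r.auc == pytest.approx(u / (n_pos * n_neg), abs=1e-12)

    def test_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(0, 1, 60)
        labels = rng.random(60) < 0.4
        labels[:2] = [True, False]  # both classes present
        r = roc_youden(scores, labels)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_independent_labels_give_half_auc(self, rng):
        n = 4000
        scores = rng.normal(0, 1, n)
        labels = rng.random(n) < 0.5
        r = roc_youden(scores, labels)
        n1, n0 = labels.sum(), (~labels).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))  # null SE of AUC
        assert abs(r.auc - 0.5) < 3 * se


class TestSteatosisLabel:
    def test_boundary_is_strict(self):
        assert steatosis_label(5.56) is False
        assert steatosis_label(5.57) is True
        assert steatosis_label(9.18) is True

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            steatosis_label(-1.0)


def _exact_signed_rank_p(diffs):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = ranks.sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    return min(1.0, ((ws <= lo).sum() + (ws >= hi).sum()) / len(ws))


class TestWilcoxonSignedRank:
    def test_symmetric_differences_give_p_one(self):
        res = wilcoxon_signed_rank([1, -1, 2, -2, 3, -3])
        assert res.p_value == pytest.approx(1.0)

    def test_all_positive_exact(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.extra["method"] == "exact"
        assert res.p_value == pytest.approx(0.03125)
        assert res.p_value == pytest.approx(_exact_signed_rank_p([1, 2, 3, 4, 5, 6]))

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            d = rng.normal(0.4, 1.0, 9)
            d = d[d != 0]
            if np.unique(np.abs(d)).size < d.size:
                continue
            res = wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(_exact_signed_rank_p(d), abs=1e-12)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert res.n == 6

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_power_under_strong_negative_shift(self):
        """n = 18 with a clear negative shift: detected in >= 95% of replicates."""
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            d = rng.normal(-1.0, 1.0, 18)
            if wilcoxon_signed_rank(d).p_value < 0.05:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_monotone_transform_invariance(self, rng):
        d = rng.normal(0.3, 1.0, 15)
        base = wilcoxon_signed_rank(d).p_value
        # any strictly increasing odd-symmetric transform preserves signed ranks
        assert wilcoxon_signed_rank(np.sign(d) * np.abs(d) ** 3).p_value == pytest.approx(base)


def _exact_rank_sum_p(a, b):
    """Exact two-sided p by enumerating all C(n_a+n_b, n_a) group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    r_obs = ranks[:n_a].sum()
    mean_r = ranks.sum() * n_a / len(pooled)
    dev = abs(r_obs - mean_r)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - mean_r) >= dev - 1e-12:
            count += 1
    return min(1.0, count / total)


class TestWilcoxonRankSum:
    def test_identical_groups_give_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_small_groups_exact(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.extra["method"] == "exact"
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(_exact_rank_sum_p([1, 2, 3], [4, 5, 6]))

    def test_exact_matches_enumeration_oracle(self, rng):
        a = rng.normal(0.8, 1.0, 6)
        b = rng.normal(0.0, 1.0, 7)
        res = wilcoxon_rank_sum(a, b)
        assert res.extra["method"] == "exact"
        assert res.p_value == pytest.approx(_exact_rank_sum_p(a, b), abs=1e-12)

    def test_u_statistic_auc_relation(self, rng):
        a = rng.normal(1, 1, 12)
        b = rng.normal(0, 1, 15)
        res = wilcoxon_rank_sum(a, b)
        r = roc_youden(
            np.concatenate([a, b]), np.r_[np.ones(12, bool), np.zeros(15, bool)]
        )
        assert res.statistic / (12 * 15) == pytest.approx(r.auc, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [1, 2, 3])

    def test_null_type_one_error_calibrated(self):
        """Type-I error at alpha = .05 over 2,000 null cohorts (21 vs 18)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            a = rng.normal(0, 1, 21)
            b = rng.normal(0, 1, 18)
            if wilcoxon_rank_sum(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


def _anova_table(n_per_arm, effect=None, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for arm, n in n_per_arm.items():
        for i in range(n):
            subj_eff = rng.normal(0, 1)
            for tp in ("baseline", "week8"):
                v = subj_eff + rng.normal(0, noise)
                if effect:
                    v += effect(arm, tp)
                rows.append(
                    {"subject_id": f"{arm}{i}", "arm": arm, "timepoint": tp, "value": v}
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_constant_values_rejected(self):
        t = _anova_table({"A": 5, "B": 5})
        t["value"] = 1.0
        with pytest.raises(ValueError):
            rm_anova_two_way(t)

    def test_incomplete_pairs_rejected(self):
        t = _anova_table({"A": 5, "B": 5}).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova_two_way(t)

    def test_arm_offset_without_time_effect(self):
        t = _anova_table(
            {"A": 12, "B": 12},
            effect=lambda arm, tp: 50.0 if arm == "B" else 0.0,
            noise=1.0,
            seed=3,
        )
        res = rm_anova_two_way(t)
        assert res["diet"].p_value < 1e-6
        assert res["interaction"].p_value > 0.01

    def test_balanced_decomposition_matches_hand_formulas(self):
        """Classic balanced mixed-design sums of squares as the oracle."""
        t = _anova_table({"A": 8, "B": 8}, effect=lambda a, tp: (2.0 if tp == "week8" else 0.0) * (1 + (a == "B")), seed=9)
        res = rm_anova_two_way(t)
        wide = t.pivot_table(index=["subject_id", "arm"], columns="timepoint", values="value")
        subj_mean = wide.mean(axis=1)
        grand = wide.to_numpy().mean()
        arms = wide.index.get_level_values("arm")
        n_g = {g: (arms == g).sum() for g in ("A", "B")}
        ss_diet = 2 * sum(n_g[g] * (subj_mean[arms == g].mean() - grand) ** 2 for g in n_g)
        ss_subj = 2 * sum(
            (subj_mean[arms == g] - subj_mean[arms == g].mean()).pow(2).sum() for g in n_g
        )
        f_diet = (ss_diet / 1) / (ss_subj / (sum(n_g.values()) - 2))
        assert res["diet"].statistic == pytest.approx(f_diet, rel=1e-6)

    def test_interaction_power_monte_carlo(self):
        """Interaction injected only in arm B week8 (effect/noise = 2, n = 18/arm):
        detected at alpha .05 in >= 90% of seeds."""
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            t = _anova_table(
                {"A": 18, "B": 18},
                effect=lambda arm, tp: 2.0 if (arm == "B" and tp == "week8") else 0.0,
                noise=1.0,
                seed=seed,
            )
            if rm_anova_two_way(t)["interaction"].p_value < 0.05:
                hits += 1
        assert hits / n_rep >= 0.90
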