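"""Gated comparisons, exact rank tests, corrections, mixed ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nicocircuit.stats import (
    adjust_pvalues,
    mixed_anova,
    normality_gated_compare,
    rank_sum_test,
)


def ranksum_enumeration_p(x, y):
    """Oracle: two-sided rank-sum p by brute enumeration over all
    C(n1+n2, n1) label assignments (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for c in itertools.combinations(range(len(pooled)), n1):
        total += 1
        hits += abs(ranks[list(c)].sum() - mu) >= obs - 1e-9
    return hits / total


class TestRankSum:
    def test_textbook_exact_case(self):
        # A = {1,2}, B = {3,4}: 2 of 6 assignments as or more extreme
        res = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert res.p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            n1 = int(rng.integers(3, 7))
            n2 = int(rng.integers(3, 13 - n1))
            x = np.round(rng.normal(0, 1, n1), 1)  # rounding makes ties likely
            y = np.round(rng.normal(0.5, 1, n2), 1)
            res = rank_sum_test(x, y)
            assert res.p == pytest.approx(ranksum_enumeration_p(x, y))

    def test_large_sample_uses_continuity_correction(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 1, 30)
        res = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue)
        assert "continuity" in res.extra["method"]

    def test_w_statistic_is_rank_sum_minus_minimum(self):
        res = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0  # U of the first sample
        res = rank_sum_test([3.0, 4.0], [1.0, 2.0])
        assert res.statistic == 4.0


class TestAdjustPvalues:
    def test_holm_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.04, 0.03], "holm"), [0.03, 0.06, 0.06]
        )

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.021], "holm")[0] == pytest.approx(0.021)
        assert adjust_pvalues([0.021], "bh")[0] == pytest.approx(0.021)

    @pytest.mark.parametrize("method", ["holm", "bh"])
    def test_never_below_raw_and_capped_at_one(self, method, rng):
        p = rng.uniform(0, 1, 15)
        adj = adjust_pvalues(p, method)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)

    @pytest.mark.parametrize("method", ["holm", "bh"])
    def test_matches_stepwise_definition(self, method, rng):
        """Oracle: hand application of the step-down / step-up rules."""
        p = np.round(rng.uniform(0, 0.2, 8), 3)
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        if method == "holm":
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, min(1.0, (m - rank) * p[i]))
                hand[i] = running
        else:
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, min(1.0, p[i] * m / rank))
                hand[i] = running
        np.testing.assert_allclose(adjust_pvalues(p, method), hand)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 1.2], "holm")


class TestGatedCompare:
    def test_gaussian_data_routes_to_welch(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(1, 2, 25)
        (res,) = normality_gated_compare([a, b])
        assert "Welch" in res.test_name
        assert res.shapiro_p >= 0.05
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_skewed_data_routes_to_rank_test(self, rng):
        a, b = rng.lognormal(0, 1.5, 25), rng.lognormal(0.5, 1.5, 25)
        (res,) = normality_gated_compare([a, b])
        assert "Wilcoxon rank sum" in res.test_name
        assert res.shapiro_p < 0.05

    def test_welch_agrees_with_pooled_t_for_equal_variances(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        t_w, p_w = sps.ttest_ind(a, b, equal_var=False)
        t_p, p_p = sps.ttest_ind(a, b, equal_var=True)
        assert t_w == pytest.approx(t_p, abs=1e-6)
        assert p_w == pytest.approx(p_p, abs=1e-4)

    def test_one_sample_design(self, rng):
        a = rng.normal(0.8, 1, 15)
        (res,) = normality_gated_compare([a], design="one_sample_vs_zero")
        assert res.test_name == "One Sample t test"
        t, p = sps.ttest_1samp(a, 0)
        assert res.statistic == pytest.approx(t)

    def test_k_sample_design_kruskal_then_holm_pairwise(self, rng):
        groups = [rng.normal(m, 1, 12) for m in (0, 0, 1.5)]
        results = normality_gated_compare(groups, design="k_sample")
        assert results[0].test_name == "Kruskal-Wallis rank sum test"
        pairwise = results[1:]
        assert len(pairwise) == 3
        raw = [r.p for r in pairwise]
        np.testing.assert_allclose(
            [r.p_adjusted for r in pairwise], adjust_pvalues(raw, "holm")
        )

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_gated_compare([[1.0, 2.0], [3.0, 4.0, 5.0]])

    def test_type_one_error_calibrated_small(self, rng):
        """Reduced-n calibration: gated two-sample engine holds its size
        under a Gaussian null (the full 2000-rep version runs in the
        acceptance suite)."""
        rej = sum(
            normality_gated_compare([rng.normal(0, 1, 20), rng.normal(0, 1, 20)])[0].p <= 0.05
            for _ in range(300)
        )
        assert 0.02 <= rej / 300 <= 0.08


class TestMixedAnova:
    def make_long(self, values):
        """values: dict (group, subject) -> list over within levels."""
        rows = []
        for (g, s), ys in values.items():
            for w, y in enumerate(ys):
                rows.append({"subject": s, "group": g, "conc": f"c{w}", "y": y})
        return pd.DataFrame(rows)

    def test_constant_response_all_f_zero(self):
        df = self.make_long(
            {(g, f"{g}{i}"): [5.0, 5.0, 5.0] for g in "AB" for i in range(4)}
        )
        results = mixed_anova(df, "y", "subject", "group", "conc")
        assert [r.statistic for r in results] == [0.0, 0.0, 0.0]
        assert [r.p for r in results] == [1.0, 1.0, 1.0]

    def test_pure_within_shift_noiseless(self):
        df = self.make_long(
            {(g, f"{g}{i}"): [1.0, 2.0, 3.0] for g in "AB" for i in range(4)}
        )
        results = {r.label: r for r in mixed_anova(df, "y", "subject", "group", "conc")}
        assert results["group (between subj)"].statistic == pytest.approx(0.0)
        within = results["conc (within subjects)"]
        assert within.statistic > 1e6 or np.isinf(within.statistic)

    def test_matches_manual_sum_of_squares(self, rng):
        """Oracle: split-plot SS decomposition computed by hand on a
        balanced 2-group x 3-level table."""
        n_per_group, b = 5, 3
        data = {}
        for gi, g in enumerate("AB"):
            for i in range(n_per_group):
                data[(g, f"{g}{i}")] = list(
                    rng.normal(10 + 2 * gi + np.arange(b) * 1.5, 2.0)
                )
        df = self.make_long(data)
        y = np.array([data[(g, f"{g}{i}")] for g in "AB" for i in range(n_per_group)])
        # y shaped (subjects, within); first 5 subjects group A
        grand = y.mean()
        group_of = np.repeat([0, 1], n_per_group)
        subj_means = y.mean(axis=1)
        group_means = np.array([subj_means[group_of == g].mean() for g in (0, 1)])
        within_means = y.mean(axis=0)
        cell_means = np.array([y[group_of == g].mean(axis=0) for g in (0, 1)])
        ss_between = b * n_per_group * np.sum((group_means - grand) ** 2)
        ss_subj = b * np.sum((subj_means - group_means[group_of]) ** 2)
        ss_within = 2 * n_per_group * np.sum((within_means - grand) ** 2)
        ss_inter = n_per_group * np.sum(
            (cell_means - group_means[:, None] - within_means[None, :] + grand) ** 2
        )
        ss_total = np.sum((y - grand) ** 2)
        ss_err = ss_total - ss_between - ss_subj - ss_within - ss_inter
        df_subj = 2 * (n_per_group - 1)
        df_err = df_subj * (b - 1)
        f_between = (ss_between / 1) / (ss_subj / df_subj)
        f_within = (ss_within / (b - 1)) / (ss_err / df_err)
        f_inter = (ss_inter / (b - 1)) / (ss_err / df_err)
        results = {r.label: r for r in mixed_anova(df, "y", "subject", "group", "conc")}
        assert results["group (between subj)"].statistic == pytest.approx(f_between, abs=1e-6)
        assert results["conc (within subjects)"].statistic == pytest.approx(f_within, abs=1e-6)
        assert results["Interaction"].statistic == pytest.approx(f_inter, abs=1e-6)

    def test_agrees_with_pingouin_on_noisy_data(self, rng):
        """Independent cross-check against pingouin's mixed ANOVA."""
        import pingouin as pg

        data = {}
        for gi, g in enumerate("AB"):
            for i in range(6):
                data[(g, f"{g}{i}")] = list(rng.normal(5 + gi, 1.5, 4))
        df = self.make_long(data)
        ours = {r.label.split(" ")[0]: r for r in mixed_anova(df, "y", "subject", "group", "conc")}
        ref = pg.mixed_anova(data=df, dv="y", subject="subject", between="group", within="conc")
        for _, row in ref.iterrows():
            key = "Interaction" if row["Source"] == "Interaction" else row["Source"]
            assert ours[key].statistic == pytest.approx(float(row["F"]), rel=1e-6)

    def test_missing_cells_rejected(self):
        df = self.make_long(
            {(g, f"{g}{i}"): [1.0, 2.0, 3.0] for g in "AB" for i in range(3)}
        )
        with pytest.raises(ValueError):
            mixed_anova(df.iloc[:-1], "y", "subject", "group", "conc")
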