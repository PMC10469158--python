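"""Relative quantification and group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cistress import (anova_oneway, collapse_technical,
                      compact_letter_display, duncan_mrt, read_ct_table,
                      relative_quantities, ttest_two_sample)
from cistress.qpcr import CtTableError, _duncan_q

from oracles import studentized_range_cdf


def ct_df(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene",
                                       "biorep", "techrep", "ct"])


def cell(group, gene, biorep, cts, sample=None):
    return [{"sample_id": sample or f"{group}_b{biorep}", "group": group,
             "gene": gene, "biorep": biorep, "techrep": i + 1, "ct": ct}
            for i, ct in enumerate(cts)]


class TestCollapseTechnical:
    def test_mean_and_flagging(self):
        df = ct_df(cell("wt", "x", 1, [20.0, 20.0, 20.0])
                   + cell("wt", "x", 2, [20.0, 21.5, 20.0])
                   + cell("wt", "x", 3, [20.0, None, 20.4]))
        out = collapse_technical(df)
        assert out["ct"].tolist() == pytest.approx([20.0, 20.5, 20.2])
        assert out["flagged"].tolist() == [False, True, False]

    def test_all_missing_cell_is_error(self):
        df = ct_df(cell("wt", "x", 1, [None, None, None]))
        with pytest.raises(CtTableError, match="biorep=1"):
            collapse_technical(df)


class TestRelativeQuantities:
    def make_means(self, dct_by_group, ref_ct=15.0):
        rows = []
        for group, dcts in dct_by_group.items():
            for b, dct in enumerate(dcts, start=1):
                rows.append({"group": group, "gene": "tgt", "biorep": b,
                             "ct": ref_ct + dct, "flagged": False})
                rows.append({"group": group, "gene": "ref", "biorep": b,
                             "ct": ref_ct, "flagged": False})
        return pd.DataFrame(rows)

    def test_ddct_zero_gives_rq_one(self):
        means = self.make_means({"wt": [5.0, 5.0, 5.0]})
        res = relative_quantities(means, "tgt", "ref", "wt")
        assert res.per_replicate["rq"].tolist() == pytest.approx([1, 1, 1])

    def test_forced_fold_four(self):
        means = self.make_means({"wt": [5.0, 5.0], "mut": [3.0, 3.0]})
        res = relative_quantities(means, "tgt", "ref", "wt")
        mut = res.per_replicate.query("group == 'mut'")
        assert mut["delta_delta_ct"].tolist() == pytest.approx([-2, -2])
        assert mut["rq"].tolist() == pytest.approx([4, 4])
        assert mut["neg_ddct"].tolist() == pytest.approx([2, 2])

    def test_neg_ddct_is_log2_rq(self):
        means = self.make_means({"wt": [5.0, 4.6], "mut": [3.3, 2.9]})
        res = relative_quantities(means, "tgt", "ref", "wt")
        per = res.per_replicate
        assert per["neg_ddct"].tolist() == pytest.approx(
            np.log2(per["rq"]).tolist())

    def test_shift_invariance_per_biorep(self):
        """Adding one cycle to target and reference of the same biorep
        leaves its rq unchanged."""
        base = self.make_means({"wt": [5.0, 5.0], "mut": [3.0, 3.5]})
        shifted = base.copy()
        mask = (shifted["group"] == "mut") & (shifted["biorep"] == 2)
        shifted.loc[mask, "ct"] += 1.0
        r0 = relative_quantities(base, "tgt", "ref", "wt")
        r1 = relative_quantities(shifted, "tgt", "ref", "wt")
        assert r0.per_replicate["rq"].tolist() == pytest.approx(
            r1.per_replicate["rq"].tolist())

    def test_missing_reference_biorep_excluded_with_warning(self):
        means = self.make_means({"wt": [5.0, 5.0], "mut": [3.0, 3.0]})
        means = means[~((means["gene"] == "ref") & (means["group"] == "mut")
                        & (means["biorep"] == 2))]
        with pytest.warns(UserWarning, match="biorep=2"):
            res = relative_quantities(means, "tgt", "ref", "wt")
        assert len(res.per_replicate.query("group == 'mut'")) == 1

    def test_missing_calibrator_is_error(self):
        means = self.make_means({"mut": [3.0, 3.0]})
        with pytest.raises(CtTableError, match="calibrator"):
            relative_quantities(means, "tgt", "ref", "wt")

    def test_summary_sem(self):
        means = self.make_means({"wt": [5.0, 5.0, 5.0],
                                 "mut": [3.0, 3.5, 2.5]})
        res = relative_quantities(means, "tgt", "ref", "wt")
        mut = res.summary.query("group == 'mut'").iloc[0]
        rqs = res.per_replicate.query("group == 'mut'")["rq"]
        assert mut["sem_rq"] == pytest.approx(rqs.std(ddof=1) / math.sqrt(3))


class TestAnova:
    def test_identical_groups(self):
        r = anova_oneway({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert r.F == 0.0 and r.p == 1.0

    def test_strong_separation(self):
        r = anova_oneway({"a": [0.0, 0.001, -0.001],
                          "b": [10.0, 10.001, 9.999]})
        assert r.p < 1e-6

    def test_hand_computed_sum_of_squares(self):
        """Balanced three-group data against an explicit SS decomposition."""
        groups = {"a": [3.0, 5.0, 4.0], "b": [8.0, 9.0, 10.0],
                  "c": [5.0, 6.0, 7.0]}
        vals = [v for g in groups.values() for v in g]
        grand = sum(vals) / 9
        ssb = 3 * sum((sum(g) / 3 - grand) ** 2 for g in groups.values())
        ssw = sum((v - sum(g) / 3) ** 2 for g in groups.values() for v in g)
        f_hand = (ssb / 2) / (ssw / 6)
        r = anova_oneway(groups)
        assert r.F == pytest.approx(f_hand)
        assert r.MSE == pytest.approx(ssw / 6)
        assert (r.df1, r.df2) == (2, 6)
        assert r.p == pytest.approx(float(stats.f.sf(f_hand, 2, 6)))
        # independent route: scipy's own one-way ANOVA
        sp = stats.f_oneway(*groups.values())
        assert r.F == pytest.approx(sp.statistic)
        assert r.p == pytest.approx(sp.pvalue)

    def test_zero_within_variance_separated_means(self):
        r = anova_oneway({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert math.isinf(r.F) and r.p == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": [1.0], "b": [1.0, 2.0]})


# Classic balanced five-group dataset (tensile strength vs cotton content,
# n = 5 per group, MSE = 8.06, df = 20) whose Duncan decisions are a
# standard textbook worked example.
COTTON = {
    "15": [7, 7, 15, 11, 9],
    "20": [12, 17, 12, 18, 18],
    "25": [14, 18, 18, 19, 19],
    "30": [19, 25, 22, 19, 23],
    "35": [7, 10, 11, 15, 11],
}


def independent_duncan_pairs(groups, alpha=0.05):
    """Step-down Duncan decisions recomputed without the implementation:
    hand sum-of-squares for MSE, quadrature studentized-range CDF for the
    critical comparison (diff significant iff its studentized statistic
    exceeds the protection-level quantile, i.e. CDF(stat) > 1 - alpha_p)."""
    k = len(groups)
    n = {g: len(v) for g, v in groups.items()}
    means = {g: sum(v) / len(v) for g, v in groups.items()}
    ssw = sum((x - means[g]) ** 2 for g, v in groups.items() for x in v)
    df = sum(n.values()) - k
    mse = ssw / df
    ordered = sorted(means, key=means.get)
    nonsig = []
    sig = set()
    for p in range(k, 1, -1):
        alpha_p = 1 - (1 - alpha) ** (p - 1)
        for i in range(k - p + 1):
            j = i + p - 1
            if any(a <= i and j <= b for a, b in nonsig):
                continue
            gi, gj = ordered[i], ordered[j]
            n_h = 2 / (1 / n[gi] + 1 / n[gj])
            stat = (means[gj] - means[gi]) / math.sqrt(mse / n_h)
            if studentized_range_cdf(stat, p, df) > 1 - alpha_p:
                sig.add(frozenset((gi, gj)))
            else:
                nonsig.append((i, j))
    return sig


class TestDuncan:
    def test_all_means_equal_no_pairs(self):
        r = duncan_mrt({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0],
                        "c": [3.0, 2.0, 1.0]})
        assert r.significant_pairs == frozenset()
        assert set(r.letters.values()) == {"a"}

    def test_two_groups_coincide_with_lsd_t_test(self):
        """For k = 2 the Duncan range criterion reduces to the two-sided
        pooled t-test at level alpha: q(alpha; 2; df) = t(1-alpha/2; df)*sqrt(2)."""
        for df in (4, 10, 30):
            q = stats.studentized_range.ppf(0.95, 2, df)
            t = stats.t.ppf(0.975, df)
            assert q == pytest.approx(t * math.sqrt(2), abs=1e-4)
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.normal(0, 1, 4)
            b = rng.normal(rng.uniform(0, 2), 1, 4)
            dec_duncan = bool(duncan_mrt({"a": a, "b": b}).significant_pairs)
            _, _, p = ttest_two_sample(a, b)
            assert dec_duncan == (p < 0.05)

    def test_extreme_separation_all_pairs(self):
        r = duncan_mrt({"a": [0.0, 0.1, -0.1], "b": [10.0, 10.1, 9.9],
                        "c": [20.0, 20.1, 19.9]})
        assert len(r.significant_pairs) == 3
        assert sorted(r.letters.values()) == ["a", "b", "c"]

    def test_textbook_worked_example_decisions(self):
        """Reproduce the classic five-group worked example: every pair
        differs except {15, 35} and {20, 25}; decisions must also agree
        with an independent step-down recomputation whose critical values
        come from the quadrature studentized-range CDF."""
        r = duncan_mrt(COTTON)
        assert r.anova.MSE == pytest.approx(8.06)
        assert r.anova.df2 == 20
        expected_ns = {frozenset(("15", "35")), frozenset(("20", "25"))}
        all_pairs = {frozenset(p) for p in itertools.combinations(COTTON, 2)}
        assert r.significant_pairs == all_pairs - expected_ns
        assert independent_duncan_pairs(COTTON) == r.significant_pairs

    def test_quantile_against_quadrature_cdf(self):
        """The quantiles driving the critical ranges are consistent with a
        direct quadrature of the studentized-range CDF."""
        for (alpha_p, p, df) in [(0.05, 2, 20), (0.0975, 3, 20),
                                 (0.142625, 4, 20)]:
            q = _duncan_q(alpha_p, p, df)
            assert studentized_range_cdf(q, p, df) == pytest.approx(
                1 - alpha_p, abs=1e-5)

    def test_unequal_n_uses_harmonic_mean(self):
        groups = {"a": [0.0, 0.2, -0.2, 0.1], "b": [1.0, 1.2, 0.8]}
        r = duncan_mrt(groups)
        assert independent_duncan_pairs(groups) == r.significant_pairs


class TestCLD:
    def test_no_pairs_all_same_letter(self):
        out = compact_letter_display({"a": 3.0, "b": 2.0, "c": 1.0}, set())
        assert set(out.values()) == {"a"}

    def test_all_pairs_distinct_letters(self):
        means = {"x": 3.0, "y": 2.0, "z": 1.0}
        pairs = {frozenset(p) for p in itertools.combinations(means, 2)}
        out = compact_letter_display(means, pairs)
        assert out == {"x": "a", "y": "b", "z": "c"}

    def test_chain_case(self):
        """A != C, A ~ B, B ~ C gives A:a, B:ab, C:b."""
        out = compact_letter_display({"A": 3.0, "B": 2.0, "C": 1.0},
                                     {frozenset(("A", "C"))})
        assert out == {"A": "a", "B": "ab", "C": "b"}

    def test_soundness_on_random_duncan_outputs(self, rng):
        """Both display conditions on decision sets produced by the range
        test on random data: significant pairs share no letter,
        non-significant pairs share at least one."""
        for _ in range(300):
            k = int(rng.integers(2, 6))
            groups = {f"g{i}": rng.normal(rng.uniform(0, 3), 1.0, 4)
                      for i in range(k)}
            r = duncan_mrt(groups)
            for a, b in itertools.combinations(groups, 2):
                shared = set(r.letters[a]) & set(r.letters[b])
                if frozenset((a, b)) in r.significant_pairs:
                    assert not shared
                else:
                    assert shared


class TestTTest:
    def test_identical_samples(self):
        t, df, p = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_strong_separation(self):
        t, df, p = ttest_two_sample([0, 0, 0, 0.001], [1, 1, 1, 1.001])
        assert p < 0.001

    def test_hand_computed_pooled_t(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        mx, my = 2.0, 4.0
        sp2 = (sum((v - mx) ** 2 for v in x)
               + sum((v - my) ** 2 for v in y)) / 4
        t_hand = (mx - my) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        t, df, p = ttest_two_sample(x, y)
        assert t == pytest.approx(t_hand)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), 4))

    def test_welch_flag(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [10.0, 30.0, 50.0]
        t_w, df_w, p_w = ttest_two_sample(x, y, welch=True)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert (t_w, p_w) == pytest.approx((ref.statistic, ref.pvalue))
        assert df_w < 4  # Welch df shrinks under variance heterogeneity

    def test_degenerate_zero_variance(self):
        t, df, p = ttest_two_sample([1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)


class TestReadCtTable:
    def test_missing_values_and_schema(self, tmp_path):
        path = tmp_path / "ct.csv"
        path.write_text("sample_id,group,gene,biorep,techrep,ct\n"
                        "s1,wt,x,1,1,20.1\ns1,wt,x,1,2,NA\ns1,wt,x,1,3,\n")
        df = read_ct_table(path)
        assert df["ct"].isna().tolist() == [False, True, True]

    def test_duplicate_rows_rejected(self, tmp_path):
        path = tmp_path / "ct.csv"
        path.write_text("sample_id,group,gene,biorep,techrep,ct\n"
                        "s1,wt,x,1,1,20.1\ns1,wt,x,1,1,20.2\n")
        with pytest.raises(CtTableError, match="duplicate"):
            read_ct_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "ct.csv"
        path.write_text("sample_id,group,gene,biorep,ct\ns1,wt,x,1,20.1\n")
        with pytest.raises(CtTableError, match="techrep"):
            read_ct_table(path)
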