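import math

import numpy as np
import pytest
from scipy import stats as sps

from spherotx.stats import (
    one_way_anova,
    significance_stars,
    studentized_range_mc_quantile,
    summarize,
    t_test,
    tukey_critical_value,
    tukey_hsd,
    two_way_anova,
)


class TestOneWayAnova:
    def test_hand_computed_decomposition(self):
        """Groups {1,2,3},{2,3,4},{3,4,5}: SSb=6, SSw=6, F=3 with df (2,6)."""
        res = one_way_anova({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        term = res.term("group")
        assert term.ss == pytest.approx(6.0)
        assert res.residual_ss == pytest.approx(6.0)
        assert term.F == pytest.approx(3.0)
        assert (term.df, res.residual_df) == (2, 6)
        assert res.total_ss == pytest.approx(term.ss + res.residual_ss)

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, size=8) for i in range(4)}
        res = one_way_anova(groups)
        ref = sps.f_oneway(*groups.values())
        assert res.term("group").F == pytest.approx(ref.statistic)
        assert res.term("group").p == pytest.approx(ref.pvalue)

    def test_two_groups_equals_t_squared(self):
        a, b = [1.0, 2.0, 4.0, 3.5], [2.0, 5.0, 4.0]
        res = one_way_anova({"a": a, "b": b})
        tt = t_test(a, b)
        assert res.term("group").F == pytest.approx(tt.statistic**2)
        assert res.term("group").p == pytest.approx(tt.p)

    def test_degenerate_variance_reported_missing(self):
        res = one_way_anova({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert math.isnan(res.term("group").F)
        assert res.diagnostics

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 observations"):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})

    def test_affine_invariance_of_p(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(i, 1, 6) for i in range(3)}
        p0 = one_way_anova(groups).term("group").p
        shifted = {k: 5.0 + 2.5 * np.asarray(v) for k, v in groups.items()}
        assert one_way_anova(shifted).term("group").p == pytest.approx(p0)


class TestTwoWayAnova:
    @staticmethod
    def _records(cells, n_rep, noise=None):
        recs = []
        rng = np.random.default_rng(0)
        for (a, b), mu in cells.items():
            for _ in range(n_rep):
                v = mu + (rng.normal(0, noise) if noise else 0.0)
                recs.append((a, b, v))
        return recs

    def test_additive_data_has_zero_interaction(self):
        cells = {(f"a{i}", f"b{j}"): 2.0 * i + 3.0 * j for i in range(3) for j in range(2)}
        res = two_way_anova(self._records(cells, 3, noise=None))
        assert res.term("interaction").ss == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_interaction(self):
        """2x2 cell means {10,10;10,14}, 2 replicates, no noise: SS_AB = 8."""
        cells = {("a1", "b1"): 10.0, ("a1", "b2"): 10.0,
                 ("a2", "b1"): 10.0, ("a2", "b2"): 14.0}
        res = two_way_anova(self._records(cells, 2))
        assert res.term("interaction").ss == pytest.approx(8.0)
        assert res.term("factor_a").ss == pytest.approx(8.0)
        assert res.term("factor_b").ss == pytest.approx(8.0)
        assert res.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_relabeling_invariance(self):
        cells = {(a, b): 1.0 + 2 * i + 3 * j + (i * j)
                 for i, a in enumerate("xy") for j, b in enumerate("uv")}
        recs = self._records(cells, 3, noise=1.0)
        res1 = two_way_anova(recs)
        swapped = [(b, a, v) for a, b, v in recs]
        res2 = two_way_anova(swapped)
        assert res1.term("factor_a").ss == pytest.approx(res2.term("factor_b").ss)
        assert res1.term("interaction").ss == pytest.approx(
            res2.term("interaction").ss
        )
        assert res1.residual_ss == pytest.approx(res2.residual_ss)

    def test_matches_statsmodels_on_balanced_design(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(11)
        recs = [
            (a, b, float(rng.normal(i + 2 * j + 0.5 * i * j, 1.0)))
            for i, a in enumerate(["a1", "a2", "a3"])
            for j, b in enumerate(["b1", "b2"])
            for _ in range(4)
        ]
        res = two_way_anova(recs)
        df = pd.DataFrame(recs, columns=["A", "B", "y"])
        ref = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", data=df).fit(), typ=2)
        assert res.term("factor_a").ss == pytest.approx(ref.loc["C(A)", "sum_sq"])
        assert res.term("factor_b").ss == pytest.approx(ref.loc["C(B)", "sum_sq"])
        assert res.term("interaction").ss == pytest.approx(
            ref.loc["C(A):C(B)", "sum_sq"]
        )
        assert res.term("interaction").p == pytest.approx(
            ref.loc["C(A):C(B)", "PR(>F)"]
        )

    def test_unbalanced_design_rejected(self):
        recs = [("a1", "b1", 1.0), ("a1", "b2", 2.0), ("a2", "b1", 3.0),
                ("a2", "b2", 4.0), ("a2", "b2", 5.0)]
        with pytest.raises(ValueError, match="unbalanced|incomplete"):
            two_way_anova(recs)


class TestTukey:
    def test_identical_means_null(self):
        res = tukey_hsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0],
                         "c": [2.0, 1.0, 3.0]})
        for pair in res.pairs:
            assert pair.q == pytest.approx(0.0)
            assert pair.p_adj == pytest.approx(1.0)
            assert not pair.significant

    def test_critical_value_against_table(self):
        """q(0.05, k=3, df=10) ≈ 3.877 (classical studentized-range table)."""
        assert tukey_critical_value(0.05, 3, 10) == pytest.approx(3.877, rel=0.01)

    def test_critical_value_against_monte_carlo(self):
        q_mc = studentized_range_mc_quantile(0.05, 3, 10, n_draws=400_000, seed=5)
        assert tukey_critical_value(0.05, 3, 10) == pytest.approx(q_mc, rel=0.02)

    def test_two_groups_reduce_to_pooled_t(self):
        """With k=2, q = |t|·√2 and the adjusted p equals the t-test p."""
        a, b = [1.0, 2.0, 3.0, 2.5], [2.0, 4.0, 3.0, 5.0]
        res = tukey_hsd({"a": a, "b": b})
        tt = t_test(a, b)
        assert res.pairs[0].q == pytest.approx(abs(tt.statistic) * math.sqrt(2))
        assert res.pairs[0].p_adj == pytest.approx(tt.p, rel=0.02)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(2)
        groups = {g: rng.normal(mu, 1.0, 6) for g, mu in
                  [("a", 0.0), ("b", 1.0), ("c", 2.5)]}
        res = tukey_hsd(groups)
        data = np.concatenate(list(groups.values()))
        labels = sum([[g] * 6 for g in groups], [])
        ref = pairwise_tukeyhsd(data, labels, alpha=0.05)
        for pair, p_ref in zip(res.pairs, ref.pvalues):
            assert pair.p_adj == pytest.approx(p_ref, abs=2e-3)

    def test_nonpositive_ms_within_rejected(self):
        with pytest.raises(ValueError, match="ms_within"):
            tukey_hsd({"a": [1.0, 2.0], "b": [3.0, 4.0]}, residual_df=2, ms_within=0.0)


class TestTTest:
    def test_hand_computed(self):
        """{1,2,3} vs {4,5,6}: pooled SD 1, SE √(2/3), t = −3/√(2/3) ≈ −3.674."""
        res = t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        ref = sps.ttest_ind([1, 2, 3], [4, 5, 6])
        assert res.p == pytest.approx(ref.pvalue)

    def test_identical_samples(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = [1.0, 3.0, 2.0], [4.0, 6.0, 5.0]
        r1, r2 = t_test(a, b), t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_welch_matches_scipy(self):
        a = [1.0, 2.0, 3.0, 8.0]
        b = [4.0, 5.0, 6.0]
        res = t_test(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == pytest.approx(ref.df)

    def test_paired_matches_scipy(self):
        a = [1.0, 2.0, 3.5, 2.0]
        b = [1.5, 2.5, 3.0, 4.0]
        res = t_test(a, b, paired=True)
        ref = sps.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_zero_variance_equal_means_missing(self):
        res = t_test([2.0, 2.0], [2.0, 2.0])
        assert math.isnan(res.statistic) and math.isnan(res.p)
        assert res.diagnostics


@pytest.mark.parametrize(
    "p,stars",
    [(0.5, "ns"), (0.04, "*"), (0.004, "**"), (0.0004, "***"), (4e-5, "****")],
)
def test_significance_stars(p, stars):
    assert significance_stars(p) == stars


def test_summarize_two_point():
    s = summarize([0.2, 0.4])
    assert s["mean"] == pytest.approx(0.3)
    assert s["sd"] == pytest.approx(0.1414, abs=1e-4)
    assert s["sem"] == pytest.approx(s["sd"] / math.sqrt(2))
    assert s["n"] == 2


def test_summarize_singleton_has_missing_dispersion():
    s = summarize([0.7])
    assert s["mean"] == 0.7 and s["n"] == 1
    assert math.isnan(s["sd"]) and math.isnan(s["sem"])
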