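"""Rank tests, normality gate, Spearman correlation, table assembly."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

from cogload.errors import DegenerateInputError, InvalidInputError
from cogload.stats import (
    comparison_table,
    mann_whitney,
    shapiro_wilk,
    significance_flag,
    spearman,
)


def brute_force_ranksum_p(x, y):
    """Oracle: enumerate every assignment of pooled values to group 1."""
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = np.array(
        [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), n1)]
    )
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_rank_sum_convention(self):
        # pooled ranks of {1,2} within {1,2,3,4} are 1 and 2
        assert mann_whitney([1, 2], [3, 4]).W == 3.0

    def test_exact_two_sided_p_small_sample(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.exact
        assert r.p == pytest.approx(2 / 6)

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (4, 2), (5, 5)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2, rng):
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + 0.5
        r = mann_whitney(x, y)
        w_oracle, p_oracle = brute_force_ranksum_p(x, y)
        assert r.W == pytest.approx(w_oracle)
        assert r.p == pytest.approx(p_oracle)

    @given(
        x=st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=20),
        y=st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=20),
    )
    def test_rank_conservation_with_ties(self, x, y):
        # W(x,y) + W(y,x) = N(N+1)/2 for any inputs, tied or not
        n = len(x) + len(y)
        try:
            w1 = mann_whitney(x, y).W
            w2 = mann_whitney(y, x).W
        except DegenerateInputError:
            # all pooled values identical: midranks still conserve
            ranks = sstats.rankdata(x + y)
            assert ranks.sum() == pytest.approx(n * (n + 1) / 2)
            return
        assert w1 + w2 == pytest.approx(n * (n + 1) / 2)

    def test_asymptotic_p_agrees_with_scipy(self, rng):
        # independent cross-check of the tie/continuity-corrected normal path
        x = rng.integers(0, 20, size=40).astype(float)
        y = rng.integers(3, 23, size=45).astype(float)
        r = mann_whitney(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
        assert not r.exact
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_descriptives_reported(self):
        r = mann_whitney([1.0, 2.0, 3.0], [4.0, 6.0])
        assert r.median1 == 2.0
        assert r.mean2 == 5.0
        assert r.n1 == 3 and r.n2 == 2

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            mann_whitney([], [1.0])


class TestShapiroWilkGate:
    def test_lognormal_sample_routes_nonparametric(self, rng):
        x = rng.lognormal(0.0, 1.0, size=500)
        r = shapiro_wilk(x)
        assert r.p < 0.001
        assert r.nonparametric

    def test_normal_sample_usually_passes(self, rng):
        x = rng.standard_normal(500)
        r = shapiro_wilk(x)
        assert 0 <= r.p <= 1  # gate decision recorded either way

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateInputError):
            shapiro_wilk([2.0] * 10)

    def test_size_bounds(self):
        with pytest.raises(InvalidInputError):
            shapiro_wilk([1.0, 2.0])


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 6, 8, 10]).rho == pytest.approx(1.0)
        assert spearman(x, [10, 8, 6, 4, 2]).rho == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r = spearman([1, 2, 3], [2, 1, 3])
        assert r.rho == pytest.approx(0.5)

    def test_exact_p_matches_permutation_oracle(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        r = spearman(x, y)
        # oracle: scipy rho on every permutation of y
        from itertools import permutations

        rhos = [
            sstats.spearmanr(x, np.asarray(p)).statistic
            for p in permutations(y)
        ]
        p_oracle = np.mean(np.abs(rhos) >= abs(r.rho) - 1e-12)
        assert r.p == pytest.approx(p_oracle)

    def test_large_n_agrees_with_scipy(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        r = spearman(x, y)
        ref = sstats.spearmanr(x, y)
        assert r.rho == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1], [1, 2, 3])


class TestComparisonTable:
    @staticmethod
    def _long(rng, measures, n=30, shift=0.5):
        import pandas as pd

        rows = []
        for m in measures:
            for cond, delta in (("low", 0.0), ("high", shift)):
                for v in rng.normal(delta, 1.0, size=n):
                    rows.append({"measure": m, "condition": cond, "value": v})
        return pd.DataFrame(rows)

    def test_row_pair_per_measure_with_paper_columns(self, rng):
        data = self._long(rng, [f"m{i}" for i in range(12)])
        table = comparison_table(data)
        assert len(table) == 24
        assert list(table.columns[:8]) == [
            "Measure", "N back", "N", "Mean", "SD", "Median", "W", "p-value",
        ]
        # stats on the first row of each pair only
        assert table["W"].notna()[::2].all()
        assert table["W"].isna()[1::2].all()

    def test_identical_data_not_significant(self, rng):
        import pandas as pd

        vals = rng.normal(size=40)
        rows = [
            {"measure": "m", "condition": c, "value": v}
            for c in ("low", "high")
            for v in vals
        ]
        table = comparison_table(pd.DataFrame(rows))
        assert table["p-value"].iloc[0] > 0.9
        assert table["sig"].iloc[0] == ""

    def test_missing_group_flagged(self, rng):
        import pandas as pd

        rows = [{"measure": "m", "condition": "low", "value": v}
                for v in rng.normal(size=5)]
        table = comparison_table(pd.DataFrame(rows))
        assert (table["flag"] == "missing-group").all()
        assert table["p-value"].isna().all()

    def test_holm_adjustment_column(self, rng):
        data = self._long(rng, ["a", "b", "c"], n=20, shift=1.0)
        table = comparison_table(data, adjust="holm")
        assert "p-adjusted" in table.columns
        padj = table["p-adjusted"].dropna()
        praw = table["p-value"].dropna()
        assert (padj.to_numpy() >= praw.to_numpy() - 1e-12).all()


def test_significance_flags_follow_conventional_levels():
    assert significance_flag(0.04) == "*"
    assert significance_flag(0.009) == "**"
    assert significance_flag(0.0009) == "***"
    assert significance_flag(0.5) == ""
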