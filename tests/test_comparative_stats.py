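import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from metapep import (assign_all, correlate_human_bacterial,
                     correlation_cluster, jaccard_cluster,
                     phylum_concordance, qvalues, ratio_group_test, shannon)
from metapep.comparative_stats import jaccard_distance
from metapep.data_io import AbundanceMatrix


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_distance({"A", "B"}, {"A", "B"}) == 0.0

    def test_disjoint_sets(self):
        assert jaccard_distance({"A"}, {"B"}) == 1.0

    def test_partial_overlap(self):
        assert jaccard_distance({"A", "B", "C"},
                                {"B", "C", "D"}) == pytest.approx(0.5)

    @given(st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15)),
           st.sets(st.integers(0, 15)))
    def test_triangle_inequality(self, a, b, c):
        if not (a or b) or not (b or c) or not (a or c):
            return
        dab = jaccard_distance(a, b)
        dbc = jaccard_distance(b, c)
        dac = jaccard_distance(a, c)
        assert dac <= dab + dbc + 1e-12

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            jaccard_cluster({"s1": set(), "s2": {"A"}})

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(1)
        presence = {f"s{i}": set(rng.choice(50, size=20, replace=False))
                    for i in range(8)}
        dend = jaccard_cluster(presence)
        heights = dend.merge_heights
        assert (np.diff(heights) >= -1e-12).all()

    def test_newick_round_trip_leaves(self):
        presence = {"s1": {"A"}, "s2": {"A", "B"}, "s3": {"C"}}
        dend = jaccard_cluster(presence)
        import dendropy
        t = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == \
            ["s1", "s2", "s3"]


class TestCorrelationCluster:
    def _matrix(self, cols):
        df = pd.DataFrame(cols)
        return AbundanceMatrix(df, scale="counts")

    def test_proportional_columns_distance_zero(self):
        m = self._matrix({"s1": [1.0, 2.0, 3.0], "s2": [2.0, 4.0, 6.0]})
        dend = correlation_cluster(m)
        assert dend.merge_heights[-1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        m = self._matrix({"s1": [1.0, 2.0, 3.0], "s2": [3.0, 2.0, 1.0]})
        dend = correlation_cluster(m)
        assert dend.merge_heights[-1] == pytest.approx(2.0)

    def test_three_columns_match_pearson_formula(self):
        cols = {"s1": [1.0, 4.0, 2.0], "s2": [2.0, 5.0, 9.0],
                "s3": [3.0, 1.0, 7.0]}
        m = self._matrix(cols)
        dend = correlation_cluster(m)
        # complete linkage root height == max pairwise 1 - r
        dmax = max(1 - stats.pearsonr(cols[a], cols[b])[0]
                   for a, b in [("s1", "s2"), ("s1", "s3"), ("s2", "s3")])
        assert dend.merge_heights[-1] == pytest.approx(dmax)

    def test_zero_variance_errors(self):
        m = self._matrix({"s1": [1.0, 1.0, 1.0], "s2": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_cluster(m)


class TestQvalues:
    def test_bh_bounds_and_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        q = qvalues(p, method="bh")
        assert ((q >= p - 1e-12) & (q <= 1.0)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_not_larger_than_bh_under_signal(self):
        p = np.concatenate([np.full(50, 1e-6),
                            np.random.default_rng(1).uniform(size=50)])
        assert (qvalues(p, "storey") <= qvalues(p, "bh") + 1e-9).all()


class TestCorrelateHumanBacterial:
    def _m(self, data, prefix):
        arr = np.atleast_2d(np.asarray(data, dtype=float))
        df = pd.DataFrame(arr,
                          index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                          columns=[f"s{j}" for j in range(arr.shape[1])])
        return AbundanceMatrix(df)

    def test_monotone_increasing_rho_one(self):
        x = np.arange(12.0)
        human = self._m([x], "H")
        bact = self._m([x ** 3], "B")
        _, full = correlate_human_bacterial(human, bact)
        assert full.rho.iloc[0] == pytest.approx(1.0)

    def test_monotone_decreasing_rho_minus_one(self):
        x = np.arange(12.0)
        human = self._m([x], "H")
        bact = self._m([np.exp(-x)], "B")
        _, full = correlate_human_bacterial(human, bact)
        assert full.rho.iloc[0] == pytest.approx(-1.0)

    def test_matches_scipy_spearman(self):
        rng = np.random.default_rng(3)
        human = self._m(rng.uniform(0, 9, size=(4, 20)), "H")
        bact = self._m(rng.uniform(0, 9, size=(5, 20)), "B")
        _, full = correlate_human_bacterial(human, bact)
        for row in full.itertuples():
            rho, p = stats.spearmanr(human.df.loc[row.human_ko],
                                     bact.df.loc[row.bacterial_ko])
            assert row.rho == pytest.approx(rho)
            assert row.p_value == pytest.approx(p, rel=1e-6)

    def test_small_n_exact_permutation(self):
        rng = np.random.default_rng(4)
        human = self._m(rng.uniform(0, 9, size=(2, 6)), "H")
        bact = self._m(rng.uniform(0, 9, size=(2, 6)), "B")
        _, full = correlate_human_bacterial(human, bact)
        assert ((full.p_value > 0) & (full.p_value <= 1)).all()

    def test_too_few_samples_errors(self):
        human = self._m(np.ones((1, 3)), "H")
        bact = self._m(np.ones((1, 3)), "B")
        with pytest.raises(ValueError, match="shared samples"):
            correlate_human_bacterial(human, bact)

    def test_null_simulation_few_discoveries(self):
        rng = np.random.default_rng(5)
        human = self._m(rng.uniform(0, 9, size=(20, 30)), "H")
        bact = self._m(rng.uniform(0, 9, size=(40, 30)), "B")
        records, _ = correlate_human_bacterial(human, bact)
        assert len(records) <= 2


def fisher_oracle(table):
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    (a, b), (c, d) = table
    r1, n = a + b, a + b + c + d
    c1 = a + c

    def prob(x):
        return (math.comb(r1, x) * math.comb(n - r1, c1 - x)
                / math.comb(n, c1))

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherViaRatioGroupTest:
    def test_oracle_examples(self):
        assert fisher_oracle([[8, 0], [0, 8]]) == pytest.approx(2 / 12870)
        assert fisher_oracle([[4, 4], [4, 4]]) == pytest.approx(1.0)

    def test_scipy_agrees_with_oracle_on_sample(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            t = rng.integers(0, 8, size=(2, 2))
            p = stats.fisher_exact(t, alternative="two-sided")[1]
            assert p == pytest.approx(fisher_oracle(t), abs=1e-12)

    def test_ratio_group_test_on_cohort(self, cohort):
        assignments = assign_all((o.peptide for o in cohort.observations),
                                 cohort.maps, cohort.tree)
        result = ratio_group_test(assignments, cohort.observations,
                                  cohort.meta)
        assert result.contingency.sum() == 16
        assert 0 <= result.fisher_p <= 1
        # null effect: the TP1-vs-TP2 check should not scream significance
        assert result.wilcoxon_p is None or result.wilcoxon_p > 0.01
        assert (result.ratios.ratio > 0).all()


class TestShannon:
    def test_uniform_four(self):
        assert shannon([25, 25, 25, 25]) == pytest.approx(math.log(4))

    def test_single_taxon(self):
        assert shannon([100.0]) == 0.0

    def test_half_quarter_quarter(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5 * math.log(2))

    def test_bounds_and_maximum(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.uniform(size=10)
            h = shannon(x)
            nz = (x > 0).sum()
            assert 0 <= h <= math.log(nz) + 1e-12

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])


class TestPhylumConcordance:
    def _percent(self, values, index, columns):
        df = pd.DataFrame(values, index=index, columns=columns)
        df = 100 * df / df.sum(axis=0)
        return AbundanceMatrix(df, scale="percent")

    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(1, 10, size=(4, 10))
        m = self._percent(vals, list("abcd"), [f"s{i}" for i in range(10)])
        per, summary = phylum_concordance(m, m)
        assert np.allclose(per.r, 1.0)
        assert set(summary.platform) == {"proteome", "16S"}

    def test_permuted_platform_r_near_zero(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(1, 10, size=(4, 40))
        cols = [f"s{i}" for i in range(40)]
        a = self._percent(vals, list("abcd"), cols)
        b = self._percent(vals[:, rng.permutation(40)], list("abcd"), cols)
        per, _ = phylum_concordance(a, b)
        assert np.abs(per.r).mean() < 0.35

    def test_one_sided_phylum_excluded(self, caplog):
        rng = np.random.default_rng(10)
        cols = [f"s{i}" for i in range(8)]
        a = self._percent(rng.uniform(1, 10, size=(3, 8)),
                          list("abc"), cols)
        b = self._percent(rng.uniform(1, 10, size=(3, 8)),
                          list("abd"), cols)
        with caplog.at_level("WARNING", logger="metapep"):
            per, _ = phylum_concordance(a, b)
        assert set(per.phylum) == {"a", "b"}
        assert any("excluded" in r.message for r in caplog.records)
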