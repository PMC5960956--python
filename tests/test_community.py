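import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microferm.community import (
    CommunityError,
    aggregate_taxonomy,
    chao1_richness,
    drop_singletons,
    expected_richness,
    merge_phylotypes,
    rarefied_richness,
    relative_abundances,
    responsive_taxa,
    shannon_index,
    time_averaged_abundance,
    validate_similarity,
)


def counts_frame(data, samples=None):
    df = pd.DataFrame(data).T
    if samples:
        df.columns = samples
    return df


class TestRelativeAbundances:
    def test_simple_proportions(self):
        counts = pd.DataFrame({"s1": [30, 70]}, index=["a", "b"])
        rel = relative_abundances(counts, remove_singletons=False)
        assert rel["s1"].tolist() == [0.3, 0.7]

    def test_singletons_removed_before_normalization(self):
        counts = pd.DataFrame({"s1": [99, 1, 0], "s2": [50, 0, 50]}, index=["a", "b", "c"])
        rel = relative_abundances(counts)
        assert "b" not in rel.index  # global count 1
        assert rel["s1"].sum() == pytest.approx(1.0)
        assert rel.loc["a", "s1"] == pytest.approx(1.0)

    def test_one_taxon_sample(self):
        counts = pd.DataFrame({"s1": [42]}, index=["a"])
        rel = relative_abundances(counts, remove_singletons=False)
        assert rel.loc["a", "s1"] == pytest.approx(1.0)

    def test_zero_total_sample_named(self):
        counts = pd.DataFrame({"bad": [0, 0]}, index=["a", "b"])
        with pytest.raises(CommunityError, match="bad"):
            relative_abundances(counts, remove_singletons=False)

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"s1": [-1, 2]}, index=["a", "b"])
        with pytest.raises(CommunityError):
            relative_abundances(counts)

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=12))
    def test_columns_sum_to_one(self, vec):
        if sum(v for v in vec if v != 1) == 0:
            return  # all mass in singletons; removal empties the sample
        counts = pd.DataFrame({"s1": vec})
        rel = relative_abundances(counts)
        assert rel["s1"].sum() == pytest.approx(1.0)


def sim_matrix(labels, pairs):
    n = len(labels)
    m = pd.DataFrame(np.zeros((n, n)), index=labels, columns=labels)
    np.fill_diagonal(m.values, 1.0)
    for a, b, v in pairs:
        m.loc[a, b] = m.loc[b, a] = v
    return m


class TestMergePhylotypes:
    def test_identity_matrix_no_change(self):
        counts = pd.DataFrame({"s1": [5, 10]}, index=["a", "b"])
        merged = merge_phylotypes(counts, sim_matrix(["a", "b"], []))
        pd.testing.assert_frame_equal(merged, counts)

    def test_pair_above_threshold_merged(self):
        counts = pd.DataFrame({"s1": [5, 10]}, index=["a", "b"])
        merged = merge_phylotypes(counts, sim_matrix(["a", "b"], [("a", "b", 0.98)]))
        assert list(merged.index) == ["b"]  # most abundant member labels the merge
        assert merged.loc["b", "s1"] == 15

    def test_single_linkage_chain(self):
        counts = pd.DataFrame({"s1": [5, 10, 7]}, index=["a", "b", "c"])
        sim = sim_matrix(
            ["a", "b", "c"], [("a", "b", 0.98), ("b", "c", 0.98), ("a", "c", 0.96)]
        )
        merged = merge_phylotypes(counts, sim)
        assert len(merged) == 1
        assert merged.iloc[0]["s1"] == 22

    def test_pair_below_threshold_kept(self):
        counts = pd.DataFrame({"s1": [5, 10]}, index=["a", "b"])
        merged = merge_phylotypes(counts, sim_matrix(["a", "b"], [("a", "b", 0.95)]))
        assert len(merged) == 2

    def test_per_sample_totals_preserved(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(8)]
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(8, 3)), index=taxa, columns=["s1", "s2", "s3"]
        )
        sim = sim_matrix(taxa, [("t0", "t3", 0.99), ("t2", "t5", 0.97), ("t5", "t7", 0.98)])
        merged = merge_phylotypes(counts, sim)
        pd.testing.assert_series_equal(merged.sum(axis=0), counts.sum(axis=0))

    def test_matrix_invariants_enforced(self):
        m = sim_matrix(["a", "b"], [])
        m.loc["a", "b"] = 0.5  # break symmetry
        counts = pd.DataFrame({"s1": [1, 2]}, index=["a", "b"])
        with pytest.raises(CommunityError, match="symmetric"):
            merge_phylotypes(counts, m)
        m2 = sim_matrix(["a", "b"], [])
        m2.loc["a", "a"] = 0.9
        with pytest.raises(CommunityError, match="diagonal"):
            validate_similarity(m2)

    def test_missing_phylotype_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["a", "b"])
        with pytest.raises(CommunityError, match="b"):
            merge_phylotypes(counts, sim_matrix(["a"], []))


class TestResponsiveTaxa:
    def test_treatment_equals_control(self, community_tables):
        treat, _, _ = community_tables
        report = responsive_taxa(treat, treat, threshold_pp=0.5)
        assert not report["responsive"].any()

    def test_family_example(self, community_tables):
        treat, ctrl, _ = community_tables
        report = responsive_taxa(treat, ctrl, threshold_pp=5.0)
        assert report.loc["famA", "responsive"]
        assert report.loc["famA", "max_increase_pp"] == pytest.approx(7.0)
        assert report.loc["famA", "at_period"] == 10.0
        assert not report.loc["famC", "responsive"]

    def test_phylotype_below_threshold(self, community_tables):
        treat, ctrl, _ = community_tables
        report = responsive_taxa(treat, ctrl, threshold_pp=2.0)
        # famC peaks at 3.5 vs 2.0 -> 1.5 pp, below the 2-pp rule
        assert report.loc["famC", "max_increase_pp"] == pytest.approx(1.5)
        assert not report.loc["famC", "responsive"]

    def test_mismatched_periods_rejected(self, community_tables):
        treat, ctrl, _ = community_tables
        with pytest.raises(CommunityError):
            responsive_taxa(treat, ctrl[[0.0, 10.0, 20.0]], threshold_pp=5.0)

    @given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=0.0, max_value=10.0))
    def test_monotone_in_threshold(self, lo, hi):
        treat = pd.DataFrame({0.0: [1.0, 2.0], 10.0: [8.0, 3.0]}, index=["x", "y"])
        ctrl = pd.DataFrame({0.0: [1.0, 2.0], 10.0: [2.0, 2.5]}, index=["x", "y"])
        lo, hi = min(lo, hi), max(lo, hi)
        at_lo = responsive_taxa(treat, ctrl, threshold_pp=lo)["responsive"]
        at_hi = responsive_taxa(treat, ctrl, threshold_pp=hi)["responsive"]
        assert set(at_hi[at_hi].index) <= set(at_lo[at_lo].index)

    def test_aggregation_commutes_with_relative_abundance(self):
        rng = np.random.default_rng(1)
        taxa = [f"pt{i}" for i in range(6)]
        counts = pd.DataFrame(
            rng.integers(2, 100, size=(6, 2)), index=taxa, columns=["s1", "s2"]
        )
        taxonomy = pd.DataFrame(
            {"phylum": "p", "family": ["f1", "f1", "f2", "f2", "f3", "f3"], "phylotype": taxa},
            index=taxa,
        )
        first = relative_abundances(
            aggregate_taxonomy(counts, taxonomy), remove_singletons=False
        )
        second = aggregate_taxonomy(
            relative_abundances(counts, remove_singletons=False), taxonomy
        )
        pd.testing.assert_frame_equal(first.sort_index(), second.sort_index())


class TestTimeAveraged:
    def test_constant_series(self):
        s = pd.Series({6.0: 10.0, 12.0: 10.0, 20.0: 10.0, 30.0: 10.0})
        assert time_averaged_abundance(s, [6.0, 12.0, 20.0, 30.0]) == pytest.approx(10.0)

    def test_arithmetic_mean(self):
        s = pd.Series({6.0: 8.0, 12.0: 12.0, 20.0: 16.0, 30.0: 24.0})
        assert time_averaged_abundance(s, [6.0, 12.0, 20.0, 30.0]) == pytest.approx(15.0)

    def test_grid_mismatch_rejected(self):
        s = pd.Series({0.0: 1.0, 6.0: 2.0, 12.0: 3.0, 20.0: 4.0, 30.0: 5.0})
        with pytest.raises(CommunityError):
            time_averaged_abundance(s, [10.0, 20.0, 30.0])


class TestShannon:
    def test_single_taxon(self):
        assert shannon_index(np.array([17])) == pytest.approx(0.0)

    def test_uniform_four_taxa(self):
        assert shannon_index(np.array([5, 5, 5, 5])) == pytest.approx(math.log(4))

    def test_hand_example(self):
        assert shannon_index(np.array([1, 1, 2])) == pytest.approx(1.0397, abs=1e-4)

    def test_zero_total_rejected(self):
        with pytest.raises(CommunityError):
            shannon_index(np.array([0, 0]))


class TestRichness:
    def test_rarefaction_full_depth_is_observed(self):
        counts = np.array([5, 3, 2, 10])
        assert rarefied_richness(counts, 20) == pytest.approx(4.0)

    def test_depth_one_yields_one(self):
        assert rarefied_richness(np.array([5, 5, 5, 5]), 1) == pytest.approx(1.0)

    def test_depth_above_total_rejected(self):
        with pytest.raises(CommunityError):
            rarefied_richness(np.array([5, 5]), 11)

    def test_nondecreasing_in_depth(self):
        counts = np.array([50, 20, 5, 2, 1, 1])
        values = [rarefied_richness(counts, d) for d in range(1, int(counts.sum()) + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_rarefaction_matches_monte_carlo(self):
        counts = np.array([12, 6, 2, 1])
        depth = 5
        rng = np.random.default_rng(42)
        pool = np.repeat(np.arange(len(counts)), counts)
        draws = [
            len(np.unique(rng.choice(pool, size=depth, replace=False)))
            for _ in range(20000)
        ]
        assert rarefied_richness(counts, depth) == pytest.approx(
            np.mean(draws), abs=0.02
        )

    def test_chao1_hand_example(self):
        # S_obs 10, F1 4, F2 2 -> 10 + 16/4 = 14
        counts = np.array([1, 1, 1, 1, 2, 2, 3, 4, 5, 6])
        assert chao1_richness(counts) == pytest.approx(14.0)

    def test_chao1_bias_corrected_no_doubletons(self):
        counts = np.array([1, 1, 1, 5])
        assert chao1_richness(counts) == pytest.approx(4 + 3 * 2 / 2)

    def test_expected_richness_dispatch(self):
        counts = np.array([5, 5])
        assert expected_richness(counts, depth=10, mode="rarefaction") == pytest.approx(2.0)
        assert expected_richness(counts, mode="chao1") == pytest.approx(2.0)
        with pytest.raises(CommunityError):
            expected_richness(counts, mode="ace")
        with pytest.raises(CommunityError):
            expected_richness(counts, mode="rarefaction")


class TestDropSingletons:
    def test_global_not_per_sample(self):
        counts = pd.DataFrame({"s1": [1, 1], "s2": [0, 1]}, index=["a", "b"])
        kept = drop_singletons(counts)
        assert list(kept.index) == ["b"]  # a totals 1, b totals 2
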