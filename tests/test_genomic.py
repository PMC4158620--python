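"""Unit and property tests for cis/trans, cooperativity, ECS and windows."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ccnet.genomic import (
    CooperativityResult,
    assign_window_genes,
    chromosome_interaction_counts,
    classify_cis_trans,
    cooperativity_test,
    ecs_sets,
    ecs_summary,
    make_windows,
    window_gpea,
)
from tests.conftest import random_graph


def exhaustive_cooperativity_pvalues(net, pos):
    """Exact permutation p over all gene-label permutations (MC limit)."""
    genes = sorted(pos.index)
    chroms = sorted(pos["chromosome"].unique())

    def count(assign):
        s = {}
        for u, v in net.edges:
            key = tuple(sorted((assign[u], assign[v])))
            s[key] = s.get(key, 0) + 1
        return s

    observed = count(dict(pos["chromosome"]))
    labels = [pos.loc[g, "chromosome"] for g in genes]
    exceed: dict = {}
    total = 0
    for perm in itertools.permutations(labels):
        total += 1
        s = count(dict(zip(genes, perm)))
        for i, a in enumerate(chroms):
            for b in chroms[i:]:
                key = (a, b)
                if s.get(key, 0) > observed.get(key, 0):
                    exceed[key] = exceed.get(key, 0) + 1
    return {k: exceed.get(k, 0) / total for k in
            [(a, b) for i, a in enumerate(chroms) for b in chroms[i:]]}, observed


class TestClassifyCisTrans:
    def test_same_chromosome_is_cis_other_is_trans(self, toy_positions):
        net = nx.Graph([("a", "b"), ("a", "d")])
        cis, trans, labels = classify_cis_trans(net, toy_positions)
        assert (cis, trans) == (1, 1)
        assert labels[("a", "b")] == "cis"
        assert labels[("a", "d")] == "trans"

    def test_unpositioned_endpoint_labeled_unmapped(self, toy_positions):
        net = nx.Graph([("a", "b"), ("a", "ghost")])
        cis, trans, labels = classify_cis_trans(net, toy_positions)
        assert labels[("a", "ghost")] == "unmapped"
        assert cis + trans + 1 == net.number_of_edges()

    def test_counts_conserve_total_edges(self, small_truth):
        net = small_truth.true_network
        cis, trans, labels = classify_cis_trans(net, small_truth.positions)
        unmapped = sum(1 for v in labels.values() if v == "unmapped")
        assert cis + trans + unmapped == net.number_of_edges()

    def test_genome_scale_percentage_arithmetic(self):
        # ratio arithmetic on the published genome-scale counts
        cis, trans = 27_345, 102_806
        assert 100 * cis / (cis + trans) == pytest.approx(21.01, abs=0.01)


class TestChromosomeInteractionCounts:
    def test_single_edge_between_two_chromosomes(self, toy_positions):
        s = chromosome_interaction_counts(nx.Graph([("a", "d")]), toy_positions)
        assert s.loc["1", "2"] == 1
        assert s.loc["2", "1"] == 1
        assert s.values.sum() == 2  # symmetric storage counts the pair twice

    def test_triangle_on_one_chromosome_counts_three(self, toy_positions):
        s = chromosome_interaction_counts(
            nx.Graph([("a", "b"), ("b", "c"), ("a", "c")]), toy_positions
        )
        assert s.loc["1", "1"] == 3

    def test_unordered_pair_total_conserves_positioned_edges(self, small_truth):
        net = small_truth.true_network
        s = chromosome_interaction_counts(net, small_truth.positions)
        iu_total = np.triu(s.values).sum()
        assert iu_total == net.number_of_edges()


class TestCooperativityTest:
    def _toy(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        pos = pd.DataFrame(
            {
                "chromosome": ["1", "1", "2", "2"],
                "start": [1, 100, 1, 100],
                "end": [50, 150, 50, 150],
            },
            index=pd.Index(["a", "b", "c", "d"], name="gene"),
        )
        return net, pos

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        net, pos = self._toy()
        exact, _ = exhaustive_cooperativity_pvalues(net, pos)
        E = 20_000
        result = cooperativity_test(net, pos, E=E, seed=123)
        for (a, b), p_exact in exact.items():
            p_mc = result.p_values.loc[a, b]
            se = math.sqrt(p_exact * (1 - p_exact) / E)
            assert abs(p_mc - p_exact) <= max(2 * se, 1e-9)

    def test_pvalue_zero_when_observation_exceeds_all_randomizations(self):
        # a clique on one chromosome, singletons elsewhere: no permutation
        # can beat the observed intra-chromosome count
        net = nx.complete_graph(4)
        net = nx.relabel_nodes(net, {i: f"g{i}" for i in range(4)})
        pos = pd.DataFrame(
            {
                "chromosome": ["1"] * 4,
                "start": [1, 10, 20, 30],
                "end": [5, 15, 25, 35],
            },
            index=pd.Index([f"g{i}" for i in range(4)], name="gene"),
        )
        result = cooperativity_test(net, pos, E=50, seed=1)
        assert result.p_values.loc["1", "1"] == 0.0

    def test_pvalues_bounded_and_symmetric(self):
        net, pos = self._toy()
        result = cooperativity_test(net, pos, E=500, seed=3)
        assert ((result.p_values.values >= 0) & (result.p_values.values <= 1)).all()
        assert np.allclose(result.p_values, result.p_values.T)
        assert (result.p_adjusted.values >= result.p_values.values - 1e-12).all()

    def test_number_of_tests_formula(self, medium_truth):
        result = cooperativity_test(
            medium_truth.true_network, medium_truth.positions, E=10, seed=0
        )
        C = len(result.s)
        assert result.n_tests == (C * C - C) // 2 + C
        assert C == 24
        assert result.n_tests == 300

    def test_deterministic_given_seed(self):
        net, pos = self._toy()
        a = cooperativity_test(net, pos, E=200, seed=9).p_values
        b = cooperativity_test(net, pos, E=200, seed=9).p_values
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_E_rejected(self):
        net, pos = self._toy()
        with pytest.raises(ValueError, match="E"):
            cooperativity_test(net, pos, E=0)


class TestECS:
    def _stats(self, edges):
        idx = pd.MultiIndex.from_tuples(sorted(edges), names=["gene_a", "gene_b"])
        return pd.DataFrame({"ecr": [edges[e] for e in sorted(edges)]}, index=idx)

    def test_all_edges_on_one_chromosome_fill_only_diagonal_set(self, toy_positions):
        stats = self._stats({("a", "b"): 0.5, ("b", "c"): 0.7})
        sets = ecs_sets(stats, toy_positions)
        non_empty = {k for k, v in sets.items() if v}
        assert non_empty == {("1", "1")}
        assert sorted(sets[("1", "1")]) == [0.5, 0.7]

    def test_set_count_for_24_chromosomes(self, medium_truth):
        stats = self._stats(
            {tuple(sorted(e)): 0.5 for e in medium_truth.true_network.edges}
        )
        sets = ecs_sets(stats, medium_truth.positions)
        summary = ecs_summary(sets)
        assert summary.n_cis_sets == 24
        assert summary.n_trans_sets == 276
        assert len(sets) == 300

    def test_sizes_conserve_positioned_edges(self, small_truth):
        stats = self._stats(
            {tuple(sorted(e)): 0.25 for e in small_truth.true_network.edges}
        )
        sets = ecs_sets(stats, small_truth.positions)
        assert sum(len(v) for v in sets.values()) == small_truth.true_network.number_of_edges()

    def test_single_set_summary_by_hand(self):
        pos = pd.DataFrame(
            {"chromosome": ["1", "1"], "start": [1, 100], "end": [10, 110]},
            index=pd.Index(["a", "b"], name="gene"),
        )
        stats = self._stats({("a", "b"): 0.2})
        sets = ecs_sets(stats, pos)
        sets[("1", "1")] = [0.2, 0.4]
        summary = ecs_summary(sets)
        assert summary.per_pair_mean.loc["1", "1"] == pytest.approx(0.3)
        assert summary.cis_median_of_means == pytest.approx(0.3)

    def test_empty_sets_reported_missing_not_zero(self, toy_positions):
        stats = self._stats({("a", "b"): 0.5})
        summary = ecs_summary(ecs_sets(stats, toy_positions))
        assert np.isnan(summary.per_pair_mean.loc["2", "2"])
        assert np.isnan(summary.trans_median_of_means)

    def test_invariant_under_chromosome_relabeling(self, toy_positions):
        stats = self._stats({("a", "b"): 0.5, ("a", "d"): 0.3, ("d", "e"): 0.9})
        base = ecs_summary(ecs_sets(stats, toy_positions))
        swapped = toy_positions.copy()
        swapped["chromosome"] = swapped["chromosome"].map({"1": "2", "2": "1"})
        other = ecs_summary(ecs_sets(stats, swapped))
        assert base.cis_median_of_means == pytest.approx(other.cis_median_of_means)
        assert sorted(base.per_pair_mean.stack().dropna()) == pytest.approx(
            sorted(other.per_pair_mean.stack().dropna())
        )


class TestMakeWindows:
    def test_example_tiling_of_short_chromosome(self):
        wins = make_windows({"1": 1_200_000}, window=1_000_000, step=500_000)
        assert [(w.start, w.end) for w in wins] == [
            (1, 1_000_000),
            (500_001, 1_200_000),
            (1_000_001, 1_200_000),
        ]

    def test_chromosome_shorter_than_window_gives_single_clipped_window(self):
        wins = make_windows({"1": 300_000}, window=1_000_000, step=500_000)
        assert [(w.start, w.end) for w in wins] == [(1, 300_000)]

    def test_consecutive_full_windows_overlap_by_window_minus_step(self):
        wins = make_windows({"1": 5_000_000}, window=1_000_000, step=500_000)
        for a, b in zip(wins, wins[1:]):
            if b.end - b.start + 1 == 1_000_000:
                assert a.end - b.start + 1 == 500_000

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"1": 10**6}, window=100, step=200)

    def test_gene_coverage_bounded_by_window_step_ratio(self, small_truth):
        cfg = small_truth.config
        wins = make_windows(cfg.chromosome_lengths, 1_000_000, 500_000)
        assign_window_genes(wins, small_truth.positions)
        counts = {}
        for w in wins:
            for g in w.genes:
                counts[g] = counts.get(g, 0) + 1
        assert set(counts) == set(small_truth.positions.index)
        assert max(counts.values()) <= math.ceil(1_000_000 / 500_000)
        assert min(counts.values()) >= 1


class TestWindowGpea:
    def _setup(self):
        # chromosome 1 holds a 5-clique within one window; chromosome 2 holds
        # scattered singletons
        net = nx.relabel_nodes(nx.complete_graph(5), {i: f"c{i}" for i in range(5)})
        net.add_edges_from([("s0", "s1")])
        pos = pd.DataFrame(
            {
                "chromosome": ["1"] * 5 + ["2"] * 2,
                "start": [10_000 * (i + 1) for i in range(5)] + [100_000, 4_000_000],
                "end": [10_000 * (i + 1) + 5_000 for i in range(5)]
                + [105_000, 4_005_000],
            },
            index=pd.Index([f"c{i}" for i in range(5)] + ["s0", "s1"], name="gene"),
        )
        wins = make_windows({"1": 5_000_000, "2": 5_000_000}, 1_000_000, 500_000)
        return net, pos, wins

    def test_clique_window_is_most_significant(self):
        net, pos, wins = self._setup()
        frame = window_gpea(net, pos, wins, min_genes=2, alpha=0.001)
        top = frame.iloc[0]
        assert top["chromosome"] == "1"
        assert top["n_edges"] == 10
        assert frame["p_value"].iloc[0] == frame["p_value"].min()

    def test_windows_below_min_genes_not_tested(self):
        net, pos, wins = self._setup()
        frame = window_gpea(net, pos, wins, min_genes=2)
        # s0 and s1 sit 3.9 Mb apart: no window holds both
        assert not ((frame["chromosome"] == "2") & (frame["n_genes"] >= 2)).any()

    def test_bonferroni_uses_number_of_tested_windows(self):
        net, pos, wins = self._setup()
        frame = window_gpea(net, pos, wins, min_genes=2)
        expected = np.minimum(frame["p_value"] * len(frame), 1.0)
        assert np.allclose(frame["p_adjusted"], expected)

    def test_gcc_flag_threshold(self):
        net, pos, wins = self._setup()
        frame = window_gpea(net, pos, wins, min_genes=2, gcc_flag_threshold=5)
        assert frame["gcc_flagged"].eq(frame["gcc_size"] >= 5).all()

    def test_min_genes_below_two_rejected(self):
        net, pos, wins = self._setup()
        with pytest.raises(ValueError):
            window_gpea(net, pos, wins, min_genes=1)
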