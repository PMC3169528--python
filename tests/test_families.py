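"""Similarity graph construction, Markov clustering, EC count matrices."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import synphen as sp
from synphen.families import cluster_species


def edge_df(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "e_value", "pct_aligned"])


class TestBuildGraph:
    def test_evalue_filter_drops_weak_edges(self):
        g = sp.build_graph(edge_df([("a", "b", 1e-3, 50.0)]))
        assert not g.has_edge("a", "b")

    def test_coverage_filter(self):
        g = sp.build_graph(edge_df([("a", "b", 1e-20, 5.0)]))
        assert not g.has_edge("a", "b")

    def test_weight_is_neg_log10(self):
        g = sp.build_graph(edge_df([("a", "b", 1e-50, 50.0)]))
        assert g["a"]["b"]["weight"] == pytest.approx(50.0)

    def test_zero_evalue_hits_cap(self):
        g = sp.build_graph(edge_df([("a", "b", 0.0, 50.0)]))
        assert g["a"]["b"]["weight"] == 200.0

    def test_reciprocal_pairs_merge_by_mean(self):
        g = sp.build_graph(edge_df([("a", "b", 1e-40, 50.0), ("b", "a", 1e-20, 50.0)]))
        assert g["a"]["b"]["weight"] == pytest.approx(30.0)

    def test_malformed_row_reports_index(self):
        with pytest.raises(ValueError, match="row 1"):
            sp.build_graph(edge_df([("a", "b", 1e-20, 50.0), ("c", "d", "bad", 50.0)]))


class TestMCL:
    def test_two_cliques_give_two_families(self):
        rows = []
        for block in ("x", "y"):
            for i in range(4):
                for j in range(i + 1, 4):
                    rows.append((f"{block}{i}", f"{block}{j}", 1e-30, 80.0))
        cs = sp.mcl(sp.build_graph(edge_df(rows)))
        assert sorted(sorted(f) for f in cs.families) == [
            ["x0", "x1", "x2", "x3"], ["y0", "y1", "y2", "y3"]]

    def test_single_node_is_singleton_family(self):
        g = nx.Graph()
        g.add_node("lonely")
        cs = sp.mcl(g)
        assert cs.families == [["lonely"]]

    def test_planted_partition_recovered(self):
        gt = sp.GraphTruth(blocks=[[f"b{b}_{i}" for i in range(6)] for b in range(5)],
                           p_within=0.9, p_between=0.0)
        edges = sp.simulate_similarity_graph(gt, seed=7)
        cs = sp.mcl(sp.build_graph(edges), inflation=1.5)
        assert sorted(sorted(f) for f in cs.families) == sorted(sorted(b) for b in gt.blocks)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_equals_connected_components_when_between_edges_absent(self, seed):
        gt = sp.GraphTruth(blocks=[[f"b{b}_{i}" for i in range(5)] for b in range(4)],
                           p_within=0.85, p_between=0.0)
        g = sp.build_graph(sp.simulate_similarity_graph(gt, seed=seed))
        cs = sp.mcl(g)
        components = sorted(sorted(c) for c in nx.connected_components(g))
        assert sorted(sorted(f) for f in cs.families) == components

    def test_partition_is_disjoint_cover(self):
        gt = sp.GraphTruth(blocks=[[f"b{b}_{i}" for i in range(4)] for b in range(3)],
                           p_within=0.8, p_between=0.3,
                           between_evalue=(1e-9, 1e-6), between_pct=(15.0, 60.0))
        g = sp.build_graph(sp.simulate_similarity_graph(gt, seed=5))
        cs = sp.mcl(g)
        members = [m for fam in cs.families for m in fam]
        assert sorted(members) == sorted(g.nodes)
        assert len(members) == len(set(members))

    def test_raising_inflation_never_merges_families(self):
        gt = sp.GraphTruth(blocks=[[f"b{b}_{i}" for i in range(5)] for b in range(3)],
                           p_within=0.7, p_between=0.15,
                           between_evalue=(1e-9, 1e-6))
        g = sp.build_graph(sp.simulate_similarity_graph(gt, seed=9))
        sizes = [len(sp.mcl(g, inflation=inf).families)
                 for inf in (1.2, 1.5, 2.0, 3.0)]
        assert sizes == sorted(sizes)

    def test_columns_stay_stochastic_throughout(self):
        gt = sp.GraphTruth(blocks=[[f"b{b}_{i}" for i in range(4)] for b in range(3)],
                           p_within=0.9, p_between=0.0)
        g = sp.build_graph(sp.simulate_similarity_graph(gt, seed=3))
        sums = []
        sp.mcl(g, inspect=lambda m: sums.append(m.sum(axis=0)))
        assert len(sums) > 1
        for s in sums:
            assert np.allclose(s, 1.0, atol=1e-9)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            sp.mcl(nx.Graph())


def _toy_clusters():
    fams = [["A1", "A2", "B1"], ["A3"], ["B2", "C1"]]
    clusters = sp.ClusterSet(families=fams, inflation=1.5, converged=True, n_iterations=5)
    gene_species = {"A1": "spA", "A2": "spA", "A3": "spA",
                    "B1": "spB", "B2": "spB", "C1": "spC"}
    gene_ec = {"A1": {"2.3.1.20"}, "A2": {"2.3.1.20"}, "B1": {"2.3.1.20"},
               "A3": {"3.1.1.3"}, "B2": {"6.2.1.1"}, "C1": {"6.2.1.3"}}
    category_map = {"2.3.1.20": "2.3.1.20", "3.1.1.3": "3.1.1.3",
                    "6.2.1.1": "6.2.1.1/2/3", "6.2.1.3": "6.2.1.1/2/3"}
    return clusters, gene_species, gene_ec, category_map


class TestECCountMatrix:
    def test_empty_clusterset_gives_zero_matrix(self):
        clusters = sp.ClusterSet(families=[], inflation=1.5, converged=True, n_iterations=0)
        m = sp.ec_count_matrix(clusters, {"g": "spA"}, {}, {"1.1.1.1": "1.1.1.1"})
        assert (m.counts.to_numpy() == 0).all()

    def test_hand_tally_single_family(self):
        clusters = sp.ClusterSet(families=[["g1", "g2", "g3"]], inflation=1.5,
                                 converged=True, n_iterations=3)
        m = sp.ec_count_matrix(
            clusters, {"g1": "spA", "g2": "spA", "g3": "spA"},
            {g: {"2.3.1.20"} for g in ("g1", "g2", "g3")},
            {"2.3.1.20": "2.3.1.20"})
        assert m.counts.loc["spA", "2.3.1.20"] == 3
        assert m.species_totals["spA"] == 3

    def test_merged_ec_category_aggregates_aliases(self):
        clusters, gsp, gec, cmap = _toy_clusters()
        m = sp.ec_count_matrix(clusters, gsp, gec, cmap)
        assert m.counts.loc["spB", "6.2.1.1/2/3"] == 1
        assert m.counts.loc["spC", "6.2.1.1/2/3"] == 1

    def test_totals_count_distinct_genes_once(self):
        clusters, gsp, gec, cmap = _toy_clusters()
        gec["A1"] = {"2.3.1.20", "3.1.1.3"}  # two ECs, one gene
        m = sp.ec_count_matrix(clusters, gsp, gec, cmap)
        assert m.species_totals["spA"] == 3

    def test_family_relabeling_and_order_invariance(self):
        clusters, gsp, gec, cmap = _toy_clusters()
        m1 = sp.ec_count_matrix(clusters, gsp, gec, cmap)
        reordered = sp.ClusterSet(families=[sorted(f, reverse=True) for f in
                                            reversed(clusters.families)],
                                  inflation=1.5, converged=True, n_iterations=5)
        m2 = sp.ec_count_matrix(reordered, gsp, gec, cmap)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)
        pd.testing.assert_series_equal(m1.species_totals, m2.species_totals)

    def test_unknown_species_is_an_error(self):
        clusters, gsp, gec, cmap = _toy_clusters()
        del gsp["C1"]
        with pytest.raises(KeyError):
            sp.ec_count_matrix(clusters, gsp, gec, cmap)

    def test_family_wide_counting_includes_members_without_own_ec(self):
        clusters = sp.ClusterSet(families=[["g1", "g2"]], inflation=1.5,
                                 converged=True, n_iterations=2)
        gsp = {"g1": "spA", "g2": "spA"}
        gec = {"g1": {"2.3.1.20"}}  # g2 has no EC of its own
        cmap = {"2.3.1.20": "2.3.1.20"}
        strict = sp.ec_count_matrix(clusters, gsp, gec, cmap)
        wide = sp.ec_count_matrix(clusters, gsp, gec, cmap, family_wide=True)
        assert strict.counts.loc["spA", "2.3.1.20"] == 1
        assert wide.counts.loc["spA", "2.3.1.20"] == 2


class TestClusterSpecies:
    def test_identical_count_vectors_at_distance_zero(self):
        counts = pd.DataFrame({"r1": [3, 3], "r2": [1, 1], "r3": [7, 7]},
                              index=["spA", "spB"])
        m = sp.ECCountMatrix(counts=counts, species_totals=pd.Series({"spA": 11, "spB": 11}))
        linkage, leaves, _ = cluster_species(m)
        assert linkage[0, 2] == pytest.approx(0.0)

    def test_display_saturates_at_15_but_counts_do_not(self):
        counts = pd.DataFrame({"1.3.99.3": [71, 2], "2.3.1.20": [10, 1]},
                              index=["R. opacus PD630", "C. glutamicum"])
        m = sp.ECCountMatrix(counts=counts,
                             species_totals=pd.Series({"R. opacus PD630": 81,
                                                       "C. glutamicum": 3}))
        assert m.display().loc["R. opacus PD630", "1.3.99.3"] == 15
        assert m.counts.loc["R. opacus PD630", "1.3.99.3"] == 71

    def test_planted_species_pairs_merge_first(self):
        counts = pd.DataFrame(
            [[10, 1, 5, 0], [11, 1, 5, 1], [0, 8, 1, 6], [1, 9, 0, 6]],
            index=["a1", "a2", "b1", "b2"],
            columns=["r1", "r2", "r3", "r4"])
        m = sp.ECCountMatrix(counts=counts, species_totals=counts.sum(axis=1))
        linkage, leaves, _ = cluster_species(m)
        first = {int(linkage[0, 0]), int(linkage[0, 1])}
        second = {int(linkage[1, 0]), int(linkage[1, 1])}
        assert {frozenset(first), frozenset(second)} == \
            {frozenset({0, 1}), frozenset({2, 3})}

    def test_single_species_rejected(self):
        counts = pd.DataFrame({"r1": [3]}, index=["spA"])
        m = sp.ECCountMatrix(counts=counts, species_totals=pd.Series({"spA": 3}))
        with pytest.raises(ValueError):
            cluster_species(m)
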