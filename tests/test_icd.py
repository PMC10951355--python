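import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from icdomain.genome_io import ExpressionTable
from icdomain.icd import (
    ICD,
    classify_response,
    cluster_icd,
    erosion_analysis,
    extract_icd,
    nearest_rank_percentile,
    state_strength,
)


def _nascent(rows):
    """Build a one-replicate-per-condition nascent table from (veh, naive, primed)."""
    df = pd.DataFrame(rows, columns=["naive_veh_1", "naive_atRA_1", "primed_atRA_1"]).astype(float)
    df.index = [f"g{i}" for i in range(len(rows))]
    return ExpressionTable(
        values=df,
        conditions={
            "naive_veh_1": "naive_veh",
            "naive_atRA_1": "naive_atRA",
            "primed_atRA_1": "primed_atRA",
        },
        spikein_factors={c: 1.0 for c in df.columns},
    )


class TestClassifyResponse:
    def test_amplified_primed_response_is_memory(self):
        resp = classify_response(_nascent([(10, 20, 50)]), pseudocount=0.0)
        assert resp.labels["g0"] == "memory"
        assert resp.lfc_response["g0"] == pytest.approx(1.0)
        assert resp.lfc_memory["g0"] == pytest.approx(math.log2(50 / 20))

    def test_unamplified_response_is_responsive_only(self):
        resp = classify_response(_nascent([(10, 20, 22)]), pseudocount=0.0)
        assert resp.labels["g0"] == "responsive"
        assert resp.lfc_memory["g0"] == pytest.approx(math.log2(22 / 20))

    def test_flat_profile_is_nonresponsive(self):
        resp = classify_response(_nascent([(10, 10, 10)]), pseudocount=0.0)
        assert resp.labels["g0"] == "nonresponsive"

    def test_infinite_cut_extremes(self):
        table = _nascent([(10, 20, 50), (10, 20, 22), (10, 10, 10)])
        all_non = classify_response(table, lfc_cut=math.inf)
        assert set(all_non.labels.values()) == {"nonresponsive"}
        rising = classify_response(_nascent([(5, 10, 20)]), lfc_cut=-math.inf)
        assert rising.labels["g0"] == "memory"

    def test_spikein_normalization_applied_before_fold_change(self):
        df = pd.DataFrame(
            {"naive_veh_1": [10.0], "naive_atRA_1": [40.0], "primed_atRA_1": [40.0]},
            index=["g0"],
        )
        table = ExpressionTable(
            values=df,
            conditions={
                "naive_veh_1": "naive_veh",
                "naive_atRA_1": "naive_atRA",
                "primed_atRA_1": "primed_atRA",
            },
            spikein_factors={"naive_veh_1": 1.0, "naive_atRA_1": 2.0, "primed_atRA_1": 1.0},
        )
        resp = classify_response(table, pseudocount=0.0)
        # normalized: 10, 20, 40 -> memory
        assert resp.labels["g0"] == "memory"

    def test_missing_condition_rejected(self):
        df = pd.DataFrame({"naive_veh_1": [1.0]}, index=["g0"])
        table = ExpressionTable(values=df, conditions={"naive_veh_1": "naive_veh"})
        with pytest.raises(KeyError):
            classify_response(table)

    def test_zero_values_require_positive_pseudocount(self):
        with pytest.raises(ValueError):
            classify_response(_nascent([(0, 5, 10)]), pseudocount=0.0)

    def test_class_partition_covers_all_genes(self):
        table = _nascent([(10, 20, 50), (10, 20, 22), (10, 10, 10), (10, 30, 90)])
        resp = classify_response(table)
        assert set(resp.labels) == set(table.genes)
        # memory genes are a subset of responsive-by-first-step genes
        for g in resp.genes("memory"):
            assert resp.lfc_response[g] > resp.lfc_cut


class TestExtractICD:
    def test_component_closure_from_promoter_bin(self, toy_network):
        toy_network.graph.nodes[("chr1", 1)]["gene_ids"] = frozenset({"gA"})
        icd = extract_icd(toy_network, "gA")
        assert set(icd.graph.nodes) == {("chr1", k) for k in (1, 2, 3, 4)}
        assert icd.genomic_order == [("chr1", k) for k in (1, 2, 3, 4)]
        assert icd.promoter_bin == ("chr1", 1)

    def test_isolated_promoter_yields_single_node_icd(self, toy_network):
        toy_network.graph.add_node(
            ("chr1", 9), element_class="P", gene_ids=frozenset({"gIso"})
        )
        icd = extract_icd(toy_network, "gIso")
        assert set(icd.graph.nodes) == {("chr1", 9)}

    def test_disjoint_component_excluded(self, toy_network):
        toy_network.graph.nodes[("chr1", 1)]["gene_ids"] = frozenset({"gA"})
        toy_network.graph.add_node(("chr1", 20), element_class="E", gene_ids=frozenset())
        toy_network.graph.add_node(("chr1", 21), element_class="E", gene_ids=frozenset())
        toy_network.graph.add_edge(("chr1", 20), ("chr1", 21), weight=3)
        icd = extract_icd(toy_network, "gA")
        assert ("chr1", 20) not in icd.graph

    def test_network_absent_gene_reported(self, toy_network):
        with pytest.raises(KeyError, match="gMissing"):
            extract_icd(toy_network, "gMissing")

    def test_every_node_reachable_from_promoter(self, default_network):
        net, _ = default_network
        for gene in ("g0000", "g0050", "g0123"):
            icd = extract_icd(net, gene)
            reach = nx.node_connected_component(icd.graph, icd.promoter_bin)
            assert reach == set(icd.graph.nodes)


def _icd_from_edges(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    order = sorted(g.nodes)
    return ICD(promoter_gene="g", promoter_bin=order[0], graph=g, genomic_order=order)


class TestClusterICD:
    def test_two_cliques_with_bridge_split_into_two_communities(self):
        nodes = [("chr1", i) for i in range(8)]
        edges = []
        for i in range(4):
            for j in range(i + 1, 4):
                edges.append((nodes[i], nodes[j], 5))
                edges.append((nodes[i + 4], nodes[j + 4], 5))
        edges.append((nodes[3], nodes[4], 1))
        part = cluster_icd(_icd_from_edges(edges), seed=0)
        assert len(set(part.coarse.values())) == 2
        assert part.modularity > 0.3
        left = {part.coarse[n] for n in nodes[:4]}
        right = {part.coarse[n] for n in nodes[4:]}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_complete_graph_is_one_community(self):
        nodes = [("chr1", i) for i in range(5)]
        edges = [(a, b, 3) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        part = cluster_icd(_icd_from_edges(edges), seed=0)
        assert len(set(part.coarse.values())) == 1

    def test_seeded_determinism(self, default_network):
        net, _ = default_network
        icd = extract_icd(net, "g0007")
        a = cluster_icd(icd, seed=3)
        b = cluster_icd(icd, seed=3)
        assert a.coarse == b.coarse and a.fine == b.fine

    def test_single_node_gives_trivial_partition(self):
        g = nx.Graph()
        g.add_node(("chr1", 0))
        icd = ICD("g", ("chr1", 0), g, [("chr1", 0)])
        part = cluster_icd(icd)
        assert part.coarse == {("chr1", 0): 0}

    def test_fine_level_refines_coarse_and_keeps_chain_only_nodes_attached(self):
        # node 2 is linked only through the genomic chain; it must stay with a
        # chain neighbour at the fine level
        nodes = [("chr1", i) for i in range(4)]
        edges = [(nodes[0], nodes[1], 5), (nodes[0], nodes[3], 5), (nodes[1], nodes[3], 5)]
        part = cluster_icd(_icd_from_edges(edges, nodes=nodes), seed=0)
        for n in nodes:
            coarse_mates = {m for m in nodes if part.coarse[m] == part.coarse[n]}
            fine_mates = {m for m in nodes if part.fine[m] == part.fine[n]}
            assert fine_mates <= coarse_mates
        if part.coarse[nodes[2]] == part.coarse[nodes[1]]:
            assert part.fine[nodes[2]] in (part.fine[nodes[1]], part.fine[nodes[3]])


class TestNearestRankPercentile:
    def test_nearest_rank_on_small_multiset(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        assert nearest_rank_percentile(values, 10) == 1
        assert nearest_rank_percentile(values, 50) == 5
        assert nearest_rank_percentile(values, 90) == 9
        assert nearest_rank_percentile(values, 100) == 10

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nearest_rank_percentile([], 50)
        with pytest.raises(ValueError):
            nearest_rank_percentile([1], 0)


class TestErosion:
    def test_hand_filtering_of_two_groups(self):
        memory = _icd_from_edges(
            [(("chr1", 0), ("chr1", 1), 1), (("chr1", 0), ("chr1", 2), 1),
             (("chr1", 1), ("chr1", 2), 2)]
        )
        responsive = _icd_from_edges([(("chr1", 10), ("chr1", 11), 8)])
        weights = [1, 1, 2, 8]
        curve = erosion_analysis(
            {"memory": [memory], "responsive": [responsive]},
            weights,
            percentiles=[75],  # nearest-rank 75th of {1,1,2,8} = 2
        )
        by_group = curve.set_index("group")
        # memory: edges below 2 removed -> promoter bin 0 loses all edges
        assert by_group.loc["memory", "promoter_fraction"] == 0.0
        assert by_group.loc["responsive", "promoter_fraction"] == 1.0

    def test_threshold_below_minimum_weight_keeps_everything(self):
        icd = _icd_from_edges([(("chr1", 0), ("chr1", 1), 5)])
        curve = erosion_analysis({"g": [icd]}, [5, 5, 9], percentiles=[10])
        assert (curve["region_fraction"] == 1.0).all()
        assert (curve["promoter_fraction"] == 1.0).all()

    def test_default_percentiles_are_deciles_10_to_90(self, default_network):
        net, _ = default_network
        icd = extract_icd(net, "g0000")
        from icdomain.icd import collect_global_weights

        curve = erosion_analysis({"g": [icd]}, collect_global_weights(net))
        assert list(curve["percentile"]) == [10, 20, 30, 40, 50, 60, 70, 80, 90]

    def test_fractions_never_increase_with_threshold(self, default_network, default_bundle):
        net, _ = default_network
        from icdomain.icd import collect_global_weights

        icds = [extract_icd(net, f"g{i:04d}") for i in range(0, 60, 3)]
        curve = erosion_analysis({"all": icds}, collect_global_weights(net))
        for col in ("region_fraction", "promoter_fraction"):
            values = curve.sort_values("percentile")[col].to_numpy()
            assert (np.diff(values) <= 1e-12).all()

    def test_empty_group_omitted_with_warning(self, caplog):
        import logging

        icd = _icd_from_edges([(("chr1", 0), ("chr1", 1), 5)])
        with caplog.at_level(logging.WARNING):
            curve = erosion_analysis({"a": [icd], "b": []}, [5], percentiles=[50])
        assert set(curve["group"]) == {"a"}
        assert any("b" in r.message for r in caplog.records)


class TestStateStrength:
    def test_ratio_arithmetic_on_known_fractions(self):
        # 10 nodes, 4 SuperEnhancer; survivors: the 3 nodes on heavy edges,
        # 2 of them SuperEnhancer -> strength (2/3)/(4/10) = 5/3
        nodes = [("chr1", i) for i in range(10)]
        edges = [(nodes[0], nodes[1], 9), (nodes[1], nodes[2], 9)]
        for i in range(3, 9):
            edges.append((nodes[i], nodes[i + 1], 1))
        icd = _icd_from_edges(edges, nodes=nodes)
        states = {nodes[0]: "SuperEnhancer", nodes[1]: "SuperEnhancer",
                  nodes[3]: "SuperEnhancer", nodes[4]: "SuperEnhancer"}
        weights = [w for _, _, w in edges]
        table = state_strength({"g": [icd]}, states, weights, percentile=90)
        se = table[table["state"] == "SuperEnhancer"].iloc[0]
        assert se["frac_unfiltered"] == pytest.approx(0.4)
        assert se["frac_filtered"] == pytest.approx(2 / 3)
        assert se["strength"] == pytest.approx((2 / 3) / 0.4)
        assert se["strength_reciprocal"] == pytest.approx(0.4 / (2 / 3))

    def test_uniform_state_has_strength_one(self):
        nodes = [("chr1", i) for i in range(4)]
        edges = [(nodes[0], nodes[1], 9), (nodes[2], nodes[3], 1)]
        icd = _icd_from_edges(edges, nodes=nodes)
        states = {n: "ActiveEnhancer" for n in nodes}
        table = state_strength({"g": [icd]}, states, [9, 1], percentile=90)
        assert table["strength"].iloc[0] == pytest.approx(1.0)

    def test_no_survivors_reported_missing(self, caplog):
        import logging

        icd = _icd_from_edges([(("chr1", 0), ("chr1", 1), 1)])
        with caplog.at_level(logging.WARNING):
            table = state_strength({"g": [icd]}, {}, [1, 50], percentile=90)
        assert table["strength"].isna().all()
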