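"""Key-driver analysis: neighborhoods, enrichment, replication, ranking."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netdriver.io_formats import MolecularNetwork
from netdriver.keydrivers import (
    filter_local_peaks,
    kd_scan,
    kd_test,
    neighborhood,
    rank_kds,
    replicate_kds,
)


def _net(edges, name="toy", directed=False):
    g = nx.DiGraph(edges) if directed else nx.Graph(edges)
    return MolecularNetwork(name=name, graph=g, directed=directed)


class TestNeighborhood:
    def test_path_graph_depth_three(self):
        net = _net([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        assert neighborhood(net, "A", 3) == {"B", "C", "D"}

    def test_isolated_node_empty(self):
        net = _net([("A", "B")])
        net.graph.add_node("Z")
        assert neighborhood(net, "Z", 3) == set()

    def test_missing_node_rejected(self):
        net = _net([("A", "B")])
        with pytest.raises(KeyError):
            neighborhood(net, "Q", 3)

    def test_directed_expanded_ignoring_direction(self):
        net = _net([("A", "B"), ("C", "B")], directed=True)
        assert neighborhood(net, "A", 2) == {"B", "C"}
        assert neighborhood(net, "A", 2, downstream_only=True) == {"B"}

    def test_matches_bfs_oracle_on_random_graph(self, rng):
        g = nx.gnp_random_graph(200, 0.02, seed=11)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        net = MolecularNetwork("rand", g)
        nodes = list(g.nodes)
        for _ in range(50):
            node = nodes[rng.integers(len(nodes))]
            depth = int(rng.integers(1, 4))
            # breadth-first oracle
            seen, frontier = {node}, {node}
            for _d in range(depth):
                frontier = {v for u in frontier for v in g.neighbors(u)} - seen
                seen |= frontier
            assert neighborhood(net, node, depth) == seen - {node}


class TestKDTest:
    def test_enriched_hub(self):
        star = [("HUB", f"L{i}") for i in range(10)]
        far = [(f"L{0}", "X1"), ("X1", "X2"), ("X2", "X3"), ("X3", "X4"), ("X4", "X5")]
        net = _net(star + far)
        k, p = kd_test(net, "HUB", {f"L{i}" for i in range(10)})
        assert k == 10 and p < 0.05

    def test_geneset_equal_to_all_nodes_is_uninformative(self):
        net = _net([("A", "B"), ("B", "C")])
        _, p = kd_test(net, "B", {"A", "B", "C"})
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_toy(self):
        g = nx.path_graph(12)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        net = MolecularNetwork("toy", g)
        gene_set = {"N1", "N2", "N5", "N8"}
        k, p = kd_test(net, "N3", gene_set)
        hood = neighborhood(net, "N3", 3)
        n, K, N = len(hood), len(gene_set - {"N3"}), 11
        expect = sum(
            math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, min(n, K) + 1)
        ) / math.comb(N, n)
        assert p == pytest.approx(expect, rel=1e-12)

    def test_invariant_under_node_relabeling(self):
        g = nx.gnp_random_graph(40, 0.1, seed=5)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        net = MolecularNetwork("a", g)
        gene_set = {f"N{i}" for i in range(0, 12)}
        _, p1 = kd_test(net, "N0", gene_set)
        mapping = {f"N{i}": f"X{i}" for i in range(40)}
        net2 = MolecularNetwork("b", nx.relabel_nodes(g, mapping))
        _, p2 = kd_test(net2, "X0", {mapping[v] for v in gene_set})
        assert p1 == pytest.approx(p2)


class TestKDScan:
    def test_star_hub_is_unique_top_driver(self):
        star = [("HUB", f"L{i}") for i in range(12)]
        # separate background component so the universe exceeds the star
        background = [("T1", "T2"), ("T2", "T3"), ("T3", "T4"), ("T4", "T5")]
        net = _net(star + background)
        scan = kd_scan(net, [f"L{i}" for i in range(12)])
        assert scan.iloc[0]["gene"] == "HUB"
        peaks = filter_local_peaks(scan, net)
        assert peaks["gene"].tolist() == ["HUB"]

    def test_empty_intersection_rejected(self):
        net = _net([("A", "B")])
        with pytest.raises(ValueError):
            kd_scan(net, ["Q", "R"])

    def test_planted_hubs_recovered(self, default_artifacts):
        truth, net = default_artifacts["truth"], default_artifacts["network"]
        causal = sorted(
            g for g, m in truth.true_partition.items()
            if m in set(truth.true_causal_modules)
        )
        scan = kd_scan(net, causal)
        peaks = filter_local_peaks(scan, net)
        assert set(truth.true_kds) == set(peaks["gene"])

    def test_correction_count_uses_candidate_pool(self):
        star = [("HUB", f"L{i}") for i in range(8)]
        net = _net(star)
        scan = kd_scan(net, ["L0", "L1"])
        pool_size = 9  # every node is within 3 of the members
        assert np.allclose(
            scan["kd_p_corrected"], np.minimum(1.0, scan["kd_p"] * pool_size)
        )


class TestReplication:
    def test_identical_network_replicates_fully(self, default_artifacts):
        truth, net = default_artifacts["truth"], default_artifacts["network"]
        causal = sorted(
            g for g, m in truth.true_partition.items()
            if m in set(truth.true_causal_modules)
        )
        scan = kd_scan(net, causal)
        frac, flags = replicate_kds(scan, net, causal)
        assert frac == pytest.approx(1.0)

    def test_rewired_network_kills_replication(self, default_artifacts):
        truth, net = default_artifacts["truth"], default_artifacts["network"]
        causal = sorted(
            g for g, m in truth.true_partition.items()
            if m in set(truth.true_causal_modules)
        )
        scan = kd_scan(net, causal)
        g2 = nx.double_edge_swap(
            net.graph.copy(), nswap=4 * net.n_edges, max_tries=10**6, seed=2
        )
        net2 = MolecularNetwork("rewired", g2)
        frac, _ = replicate_kds(scan, net2, causal)
        assert frac < 0.2


class TestRanking:
    def _records(self):
        return pd.DataFrame(
            {
                "gene": ["KD_GWAS", "KD_TWAS", "KD_OTHER"],
                "network": ["ppi"] * 3,
                "neighborhood_size": [50, 40, 30],
                "overlap_count": [20, 15, 10],
                "kd_p": [1e-8, 1e-10, 1e-6],
                "kd_p_corrected": [1e-5, 1e-7, 1e-3],
                "significant": [True, True, True],
            }
        )

    def _esnp_gwas(self):
        esnp = pd.DataFrame(
            {
                "snp_id": ["S1", "S2"],
                "gene_id": ["KD_GWAS", "KD_OTHER"],
                "kind": ["cis", "cis"],
                "eqtl_p": [1e-6, 1e-6],
                "eqtl_fdr": [0.01, 0.01],
            }
        )
        gwas = pd.DataFrame(
            {"snp_id": ["S1", "S2"], "p_sbp": [1.6e-14, 0.3], "p_dbp": [0.5, 0.4]}
        ).set_index("snp_id")
        return esnp, gwas

    def _twas(self):
        # 100-gene transcriptome; KD_TWAS passes 0.05/100
        rows = [("KD_TWAS", "sbp", 1.0, 0.9, 1e-7, True)]
        rows += [(f"G{i}", "sbp", 0.0, 0.0, 0.5, False) for i in range(99)]
        return pd.DataFrame(
            rows, columns=["gene_id", "trait", "beta", "r", "p", "bonferroni_significant"]
        )

    def test_tier_assignment_and_order(self):
        esnp, gwas = self._esnp_gwas()
        ranked = rank_kds(self._records(), esnp, gwas, self._twas())
        assert ranked["gene"].tolist() == ["KD_GWAS", "KD_TWAS", "KD_OTHER"]
        assert ranked["tier"].tolist() == ["GWAS", "TWAS", "OTHER"]
        assert ranked.loc[0, "min_esnp_gwas_p"] == pytest.approx(1.6e-14)
        assert ranked["rank"].tolist() == [1, 2, 3]

    def test_no_tier_criteria_all_other_sorted_by_kd_p(self):
        recs = self._records()
        esnp = pd.DataFrame(columns=["snp_id", "gene_id", "kind", "eqtl_p", "eqtl_fdr"])
        gwas = pd.DataFrame({"snp_id": [], "p_sbp": []}).set_index("snp_id")
        twas = pd.DataFrame(
            [("GX", "sbp", 0.0, 0.0, 0.9, False)],
            columns=["gene_id", "trait", "beta", "r", "p", "bonferroni_significant"],
        )
        ranked = rank_kds(recs, esnp, gwas, twas)
        assert set(ranked["tier"]) == {"OTHER"}
        assert ranked["gene"].tolist() == ["KD_TWAS", "KD_GWAS", "KD_OTHER"]

    def test_multi_network_tier(self):
        recs = pd.concat(
            [self._records(), self._records().assign(network="bn")], ignore_index=True
        )
        esnp = pd.DataFrame(columns=["snp_id", "gene_id", "kind", "eqtl_p", "eqtl_fdr"])
        gwas = pd.DataFrame({"snp_id": [], "p_sbp": []}).set_index("snp_id")
        twas = pd.DataFrame(
            [("GX", "sbp", 0.0, 0.0, 0.9, False)],
            columns=["gene_id", "trait", "beta", "r", "p", "bonferroni_significant"],
        )
        ranked = rank_kds(recs, esnp, gwas, twas)
        assert set(ranked["tier"]) == {"MULTI"}
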