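import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_graph_edges
from trophonet.community import AbundanceTable
from trophonet.network import (
    CooccurrenceNetwork,
    build_network,
    compare_topologies,
    cross_kingdom_composition,
    filter_low_abundance,
    topology,
)
from trophonet.stats import bh_fdr, spearman_pvalue


def net_from_edges(edges, nodes=None, signs=None, kingdoms=None):
    g = nx.Graph()
    nodes = nodes if nodes is not None else sorted({v for e in edges for v in e})
    for v in nodes:
        g.add_node(v, kingdom=(kingdoms or {}).get(v, "bacteria"))
    for k, (u, v) in enumerate(edges):
        sign = (signs or {}).get((u, v), "+")
        g.add_edge(u, v, rho=0.9 if sign == "+" else -0.9, sign=sign, q=0.01)
    return CooccurrenceNetwork(graph=g)


def make_table(counts, kingdoms, group=None):
    counts = pd.DataFrame(counts, dtype=float)
    counts.index = [f"t{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    taxonomy = pd.DataFrame(
        {"kingdom": kingdoms, "phylum": ["X"] * len(kingdoms)}, index=counts.index
    )
    g = pd.Series(group, index=counts.columns) if group else None
    return AbundanceTable(counts=counts, taxonomy=taxonomy, group=g)


class TestFilterLowAbundance:
    def test_strictly_above_rule(self):
        # grand total 10,000: taxon at 0.02% kept, taxon at exactly 0.01% dropped
        counts = [[2], [1], [9997]]
        t = make_table(counts, ["bacteria"] * 3)
        out = filter_low_abundance(t, min_rel=0.0001)
        assert list(out.taxa) == ["t0", "t2"]

    def test_identity_when_all_pass(self):
        t = make_table([[10], [20]], ["bacteria"] * 2)
        out = filter_low_abundance(t, min_rel=0.0001)
        assert list(out.taxa) == ["t0", "t1"]

    def test_per_kingdom_denominator(self):
        # the rare phytoplankter is abundant relative to its own kingdom
        counts = [[1000000], [5], [10]]
        t = make_table(counts, ["bacteria", "bacteria", "phytoplankton"])
        out = filter_low_abundance(t, min_rel=0.001)
        assert "t2" in set(out.taxa)
        assert "t1" not in set(out.taxa)

    def test_empty_result_is_error(self):
        t = make_table([[1], [1]], ["bacteria"] * 2)
        with pytest.raises(ValueError, match="threshold"):
            filter_low_abundance(t, min_rel=0.9)


class TestBuildNetwork:
    def test_identical_ranks_form_triangle(self):
        # three co-varying taxa riding on a large stable background, so the
        # per-kingdom closure leaves their ranks intact
        base = np.arange(1.0, 13.0)
        background = np.full(12, 1e6)
        counts = np.vstack([base, base * 3, np.exp(base / 2), background])
        t = make_table(counts, ["bacteria"] * 4)
        net = build_network(t)
        for u, v in [("t0", "t1"), ("t0", "t2"), ("t1", "t2")]:
            assert net.graph.has_edge(u, v)
            assert net.graph.edges[u, v]["sign"] == "+"

    def test_opposite_ranks_negative_edge(self):
        base = np.arange(1.0, 13.0)
        rng = np.random.default_rng(0)
        noise = rng.normal(size=(2, 12))
        counts = np.vstack([base, base[::-1], 10 + noise])
        t = make_table(counts, ["bacteria"] * 4)
        net = build_network(t)
        assert net.graph.has_edge("t0", "t1")
        assert net.graph.edges["t0", "t1"]["sign"] == "-"

    def test_double_gate_holds_post_hoc(self, group_networks, combined_table):
        """Every retained edge re-tests above both thresholds."""
        net = group_networks["M"]
        samples = combined_table.samples_in_group("M")
        kingdoms = combined_table.taxonomy.loc[combined_table.taxa, "kingdom"]
        rel = {}
        for kingdom in ("phytoplankton", "bacteria"):
            taxa_k = combined_table.taxa[kingdoms.values == kingdom]
            sub = combined_table.counts.loc[taxa_k, samples]
            rel.update({t: sub.loc[t] / sub.sum(axis=0) for t in taxa_k})
        edges = list(net.graph.edges(data=True))
        assert len(edges) > 0
        raw_ps = []
        for u, v, d in edges:
            rho, p = spearman_pvalue(rel[u].to_numpy(), rel[v].to_numpy())
            assert abs(rho) >= net.threshold_r
            assert rho == pytest.approx(d["rho"], abs=1e-12)
            raw_ps.append(p)
        # retained q's were computed over the full family; each must beat alpha
        assert all(d["q"] < net.alpha_fdr for _, _, d in edges)

    def test_isolated_taxa_stay_as_nodes(self, group_networks, combined_table):
        net = group_networks["L"]
        assert net.n_nodes == len(combined_table.taxa)
        assert net.n_nodes > net.graph.number_of_nodes() - 1  # sanity

    def test_too_few_samples(self):
        t = make_table(np.ones((3, 3)), ["bacteria"] * 3)
        with pytest.raises(ValueError, match="at least 4"):
            build_network(t)


class TestTopology:
    def test_path_graph(self):
        net = net_from_edges([(0, 1), (1, 2), (2, 3)])
        top = topology(net)
        assert top.diameter == 3
        assert top.avg_degree == pytest.approx(1.5)
        assert top.clustering_coefficient == 0.0
        assert top.avg_path_length == pytest.approx(5 / 3)

    def test_two_disjoint_triangles(self):
        net = net_from_edges([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        top = topology(net)
        assert top.clustering_coefficient == pytest.approx(1.0)
        # exhaustive search over all partitions of 6 nodes gives Q = 0.5
        edges = list(net.graph.edges())
        assert oracles.max_modularity(edges, list(net.graph.nodes())) == pytest.approx(0.5)
        assert top.modularity == pytest.approx(0.5, abs=1e-9)
        assert top.n_components == 2

    def test_complete_graph_k5(self):
        net = net_from_edges([(i, j) for i in range(5) for j in range(i + 1, 5)])
        top = topology(net)
        assert top.clustering_coefficient == pytest.approx(1.0)
        assert top.diameter == 1
        best = oracles.max_modularity(list(net.graph.edges()), list(net.graph.nodes()))
        assert top.modularity == pytest.approx(best, abs=1e-9)
        assert top.modularity == pytest.approx(0.0, abs=1e-9)

    def test_louvain_matches_exhaustive_on_small_graphs(self):
        rng = np.random.default_rng(21)
        checked = 0
        for _ in range(25):
            n = int(rng.integers(4, 9))
            edges = random_graph_edges(rng, n, 0.45)
            if not edges:
                continue
            net = net_from_edges(edges, nodes=list(range(n)))
            top = topology(net, louvain_restarts=10, seed=3)
            best = oracles.max_modularity(edges, list(range(n)))
            assert top.modularity == pytest.approx(best, abs=1e-9)
            checked += 1
        assert checked >= 15

    def test_path_metrics_match_floyd_warshall(self):
        rng = np.random.default_rng(22)
        for _ in range(8):
            n = int(rng.integers(10, 51))
            edges = random_graph_edges(rng, n, 0.08)
            if not edges:
                continue
            net = net_from_edges(edges, nodes=list(range(n)))
            top = topology(net)
            adj = np.zeros((n, n))
            for u, v in edges:
                adj[u, v] = adj[v, u] = 1
            diam, apl = oracles.path_metrics(adj)
            assert top.diameter == diam
            assert top.avg_path_length == pytest.approx(apl, abs=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(23)
        edges = random_graph_edges(rng, 12, 0.3)
        net = net_from_edges(edges, nodes=list(range(12)))
        mapping = {i: f"taxon_{(i * 7) % 12}" for i in range(12)}
        relabeled = CooccurrenceNetwork(graph=nx.relabel_nodes(net.graph, mapping))
        a = topology(net, seed=1)
        b = topology(relabeled, seed=1)
        for metric in ("n_edges", "avg_degree", "diameter",
                       "clustering_coefficient", "avg_path_length", "modularity"):
            assert getattr(a, metric) == pytest.approx(getattr(b, metric), abs=1e-9)

    def test_empty_network_flagged(self):
        net = net_from_edges([], nodes=[0, 1, 2])
        top = topology(net)
        assert top.empty
        assert top.n_edges == 0

    def test_signed_percentages(self):
        net = net_from_edges(
            [(0, 1), (1, 2), (2, 3)], signs={(1, 2): "-"}
        )
        top = topology(net)
        assert top.pct_positive_edges == pytest.approx(200 / 3)
        assert top.pct_negative_edges == pytest.approx(100 / 3)
        assert top.pct_positive_edges + top.pct_negative_edges == pytest.approx(100.0)


class TestCrossKingdom:
    def test_fraction_accounting(self):
        kingdoms = {0: "bacteria", 1: "bacteria", 2: "phytoplankton",
                    3: "phytoplankton", 4: "bacteria"}
        net = net_from_edges(
            [(0, 1), (2, 3), (0, 2), (4, 3)], kingdoms=kingdoms
        )
        comp = cross_kingdom_composition(net)
        bp = comp[comp["edge_type"] == "BP"]["count"].sum()
        assert bp == 2
        assert comp["count"].sum() == 4
        assert comp["fraction_of_edges"].sum() == pytest.approx(1.0)

    def test_all_bacterial_flagged(self):
        net = net_from_edges([(0, 1)], kingdoms={0: "bacteria", 1: "bacteria"})
        comp = cross_kingdom_composition(net)
        assert comp.attrs.get("flag") == "no cross-kingdom edges"

    def test_unlabeled_node_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", rho=0.9, sign="+", q=0.01)
        net = CooccurrenceNetwork(graph=g)
        with pytest.raises(ValueError, match="a|b"):
            cross_kingdom_composition(net)

    def test_counts_sum_to_edges(self, group_networks):
        for net in group_networks.values():
            comp = cross_kingdom_composition(net)
            assert comp["count"].sum() == net.n_edges


class TestCompareTopologies:
    def test_trend_flags(self):
        import dataclasses

        base = topology(net_from_edges([(0, 1), (1, 2)]))
        tops = [
            dataclasses.replace(base, group=g, modularity=m, pct_negative_edges=nn)
            for g, m, nn in [("L", 0.641, 0.32), ("M", 0.598, 0.36), ("H", 0.558, 0.61)]
        ]
        trends = compare_topologies(tops).set_index("metric")
        assert trends.loc["modularity", "trend"] == "decreasing"
        assert trends.loc["pct_negative_edges", "trend"] == "increasing"

    def test_flat_flag(self):
        import dataclasses

        base = topology(net_from_edges([(0, 1), (1, 2)]))
        tops = [dataclasses.replace(base, group=g, modularity=0.5) for g in "LMH"]
        trends = compare_topologies(tops).set_index("metric")
        assert trends.loc["modularity", "trend"] == "flat"

    def test_needs_two_groups(self):
        base = topology(net_from_edges([(0, 1)]))
        with pytest.raises(ValueError):
            compare_topologies([base])
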