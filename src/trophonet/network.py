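"""Signed plankton–bacteria co-occurrence networks and their topology.

Edges are retained under a double gate: Spearman |rho| ≥ threshold (default
0.6) AND Benjamini–Hochberg FDR-adjusted p < alpha (default 0.05), computed
per trophic group on per-kingdom relative abundances.  Spearman's rank
invariance is what makes microscopy cell densities and sequencing read
counts commensurable in one correlation matrix — it is the only supported
edge statistic.

Topology metrics follow the Gephi conventions: computed on the unsigned
simple graph; diameter and average path length on the largest connected
component; mean local clustering counting degree-<2 nodes as 0; modularity
from Louvain with seeded restarts, best Q kept.  Edge sign is carried as an
attribute and used only for signed percentages and cross-kingdom
composition.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .community import AbundanceTable, relative_abundance
from .stats import correlation_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceNetwork",
    "NetworkTopology",
    "filter_low_abundance",
    "build_network",
    "topology",
    "cross_kingdom_composition",
    "compare_topologies",
]

EDGE_TYPES = ("BB", "PP", "BP")


@dataclass
class CooccurrenceNetwork:
    """Signed, thresholded correlation graph over taxa.

    ``graph`` is an undirected simple networkx Graph whose nodes carry
    ``kingdom`` (and ``phylum`` when known) and whose edges carry ``rho``,
    ``sign`` ('+'/'−' by the sign of rho) and ``q``.  Isolated taxa that
    passed the abundance filter remain as nodes, matching the convention
    that the node set is fixed across trophic groups.
    """

    graph: nx.Graph
    group: str | None = None
    threshold_r: float = 0.6
    alpha_fdr: float = 0.05

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {"taxon_i": u, "taxon_j": v, "rho": d["rho"], "sign": d["sign"], "q": d["q"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "rho", "sign", "q"])


@dataclass(frozen=True)
class NetworkTopology:
    """Topology metric bundle for one co-occurrence network."""

    group: str | None
    n_nodes: int
    n_edges: int
    avg_degree: float
    diameter: int
    clustering_coefficient: float
    modularity: float
    avg_path_length: float
    pct_positive_edges: float
    pct_negative_edges: float
    n_components: int
    largest_component_size: int
    empty: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_low_abundance(table: AbundanceTable, min_rel: float = 0.0001) -> AbundanceTable:
    """Keep taxa whose overall relative abundance strictly exceeds ``min_rel``.

    The share is taxon total / grand total *within its kingdom*, so read
    depth never dilutes cell densities or vice versa.  A taxon at exactly
    the threshold is removed (strict "above").
    """
    kingdoms = table.taxonomy.loc[table.taxa, "kingdom"]
    keep = []
    for kingdom in kingdoms.unique():
        taxa_k = table.taxa[kingdoms.values == kingdom]
        sub = table.counts.loc[taxa_k]
        grand = float(sub.to_numpy().sum())
        if grand <= 0:
            raise ValueError(f"kingdom {kingdom!r} has zero total abundance")
        share = sub.sum(axis=1) / grand
        keep.extend(share.index[share > min_rel].tolist())
    if not keep:
        raise ValueError(
            f"no taxon exceeds relative abundance {min_rel}; lower the threshold"
        )
    kept = [t for t in table.taxa if t in set(keep)]  # preserve original order
    return table.subset_taxa(kept)


def build_network(
    table: AbundanceTable,
    group: str | None = None,
    threshold_r: float = 0.6,
    alpha: float = 0.05,
) -> CooccurrenceNetwork:
    """Build the signed co-occurrence network for one trophic group.

    Counts are converted to per-kingdom relative abundances over the
    group's samples, correlated with tie-aware Spearman, and gated on
    |rho| ≥ threshold_r AND BH q < alpha over the full pair family.
    """
    if not 0 < threshold_r <= 1:
        raise ValueError("threshold_r must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sub = table.subset_samples(table.samples_in_group(group)) if group is not None else table
    if len(sub.samples) < 4:
        raise ValueError(
            f"group {group!r} has {len(sub.samples)} samples; need at least 4"
        )
    kingdoms = sub.taxonomy.loc[sub.taxa, "kingdom"]
    present = set(kingdoms.unique())
    if len(present) < 2:
        logger.warning("only one kingdom (%s) present; no cross-kingdom edges possible",
                       ", ".join(sorted(present)))
    # per-kingdom relative abundance, then one matrix over all taxa
    blocks = []
    for kingdom in kingdoms.unique():
        taxa_k = sub.taxa[kingdoms.values == kingdom]
        blocks.append(relative_abundance(sub.subset_taxa(taxa_k), level="taxon"))
    rel = pd.concat(blocks).loc[sub.taxa]
    pairs = correlation_matrix(rel)
    g = nx.Graph()
    for t in sub.taxa:
        row = sub.taxonomy.loc[t]
        g.add_node(t, kingdom=str(row["kingdom"]),
                   phylum=str(row.get("phylum", "")))
    hits = pairs[(pairs["rho"].abs() >= threshold_r) & (pairs["q"] < alpha)]
    for _, r in hits.iterrows():
        g.add_edge(
            r["taxon_i"], r["taxon_j"],
            rho=float(r["rho"]),
            sign="+" if r["rho"] > 0 else "-",
            q=float(r["q"]),
        )
    return CooccurrenceNetwork(graph=g, group=group,
                               threshold_r=threshold_r, alpha_fdr=alpha)


#: node count up to which modularity is maximized exactly instead of by
#: Louvain (Bell(8) = 4140 partitions — exhaustive search is instantaneous,
#: and the greedy heuristic can be trapped below the optimum on tiny graphs)
EXACT_MODULARITY_MAX_NODES = 8


def _exact_max_q(g: nx.Graph) -> float:
    """Exhaustive modularity maximization via restricted-growth-string
    enumeration of all set partitions."""
    nodes = list(g.nodes)
    n = len(nodes)
    best = -math.inf
    rgs = [0] * n  # restricted growth string; rgs[i] = community of node i
    maxes = [0] * n

    def q_of(assign):
        comms: dict[int, set] = {}
        for node, c in zip(nodes, assign):
            comms.setdefault(c, set()).add(node)
        return nx.community.modularity(g, comms.values(), resolution=1.0)

    while True:
        best = max(best, q_of(rgs))
        # next restricted growth string
        i = n - 1
        while i > 0 and rgs[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return best
        rgs[i] += 1
        maxes[i] = max(maxes[i - 1], rgs[i])
        for j in range(i + 1, n):
            rgs[j] = 0
            maxes[j] = maxes[i]


def _best_modularity_q(g: nx.Graph, restarts: int, base_seed: int) -> float:
    if g.number_of_nodes() <= EXACT_MODULARITY_MAX_NODES:
        return _exact_max_q(g)
    best = -math.inf
    for k in range(restarts):
        parts = nx.community.louvain_communities(g, seed=base_seed + k, resolution=1.0)
        q = nx.community.modularity(g, parts, resolution=1.0)
        best = max(best, q)
    return best


def topology(
    network: CooccurrenceNetwork,
    louvain_restarts: int = 10,
    seed: int = 0,
) -> NetworkTopology:
    """Compute the topology metric bundle for one network."""
    g = network.graph
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0 or m == 0:
        return NetworkTopology(
            group=network.group, n_nodes=n, n_edges=m, avg_degree=0.0,
            diameter=0, clustering_coefficient=0.0, modularity=0.0,
            avg_path_length=0.0, pct_positive_edges=0.0, pct_negative_edges=0.0,
            n_components=n, largest_component_size=min(n, 1), empty=True,
        )
    components = list(nx.connected_components(g))
    giant = g.subgraph(max(components, key=len))
    if len(components) > 1:
        logger.info("network has %d components; path metrics use the largest (%d nodes)",
                    len(components), giant.number_of_nodes())
    if giant.number_of_nodes() > 1:
        diameter = nx.diameter(giant)
        apl = nx.average_shortest_path_length(giant)
    else:
        diameter, apl = 0, 0.0
    signs = [d["sign"] for _, _, d in g.edges(data=True)]
    n_pos = signs.count("+")
    return NetworkTopology(
        group=network.group,
        n_nodes=n,
        n_edges=m,
        avg_degree=2.0 * m / n,
        diameter=int(diameter),
        clustering_coefficient=float(nx.average_clustering(g)),
        modularity=float(_best_modularity_q(g, louvain_restarts, seed)),
        avg_path_length=float(apl),
        pct_positive_edges=100.0 * n_pos / m,
        pct_negative_edges=100.0 * (m - n_pos) / m,
        n_components=len(components),
        largest_component_size=giant.number_of_nodes(),
    )


def cross_kingdom_composition(
    network: CooccurrenceNetwork, taxonomy: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Classify each edge as BB, PP or BP and tabulate counts by sign.

    BB = bacteria–bacteria, PP = phytoplankton–phytoplankton, BP =
    cross-kingdom.  Fractions are reported both over all retained edges
    and within each sign class.  Kingdom labels come from node attributes,
    falling back to ``taxonomy`` (indexed by taxon_id, column ``kingdom``).
    """
    g = network.graph

    def kingdom(node) -> str:
        k = g.nodes[node].get("kingdom")
        if (not k) and taxonomy is not None and node in taxonomy.index:
            k = str(taxonomy.loc[node, "kingdom"])
        if not k:
            raise ValueError(f"node {node!r} has no kingdom label")
        return k

    counts = {(t, s): 0 for t in EDGE_TYPES for s in ("+", "-")}
    for u, v, d in g.edges(data=True):
        ku, kv = kingdom(u), kingdom(v)
        if ku == kv:
            etype = "BB" if ku == "bacteria" else "PP"
        else:
            etype = "BP"
        counts[(etype, d["sign"])] += 1
    total = sum(counts.values())
    sign_totals = {s: sum(counts[(t, s)] for t in EDGE_TYPES) for s in ("+", "-")}
    rows = []
    for t in EDGE_TYPES:
        for s in ("+", "-"):
            c = counts[(t, s)]
            rows.append({
                "edge_type": t,
                "sign": s,
                "count": c,
                "fraction_of_edges": c / total if total else 0.0,
                "fraction_within_sign": c / sign_totals[s] if sign_totals[s] else 0.0,
            })
    out = pd.DataFrame(rows)
    out.attrs["n_edges"] = total
    if total and out.loc[out["edge_type"] == "BP", "count"].sum() == 0:
        out.attrs["flag"] = "no cross-kingdom edges"
    return out


#: metrics whose L→H direction is reported by compare_topologies
TREND_METRICS = (
    "n_edges", "avg_degree", "diameter", "clustering_coefficient",
    "modularity", "avg_path_length", "pct_positive_edges", "pct_negative_edges",
)


def compare_topologies(
    topologies: list[NetworkTopology], atol: float = 1e-12
) -> pd.DataFrame:
    """Per-metric values and monotonicity flags across ordered groups (L<M<H).

    Flags: ``decreasing`` / ``increasing`` (strict throughout),
    ``flat`` (all equal within atol), ``non-monotone`` otherwise.
    """
    if len(topologies) < 2:
        raise ValueError("need at least 2 group topologies to compare")
    rows = []
    for metric in TREND_METRICS:
        vals = [getattr(t, metric) for t in topologies]
        diffs = np.diff(vals)
        if np.all(np.abs(diffs) <= atol):
            flag = "flat"
        elif np.all(diffs > atol):
            flag = "increasing"
        elif np.all(diffs < -atol):
            flag = "decreasing"
        else:
            flag = "non-monotone"
        row = {"metric": metric, "trend": flag}
        for t, v in zip(topologies, vals):
            row[str(t.group)] = v
        rows.append(row)
    return pd.DataFrame(rows)
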