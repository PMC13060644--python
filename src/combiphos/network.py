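"""Interaction-network target prioritization.

Significant features' proteins are placed on a STRING-style interaction graph
(induced subgraph, unweighted edges gated by a confidence threshold, default
0.15 = low confidence).  Unweighted shortest-path betweenness centrality
identifies signalling bottlenecks; greedy modularity maximization partitions
the graph into communities; and nodes are ranked by the product of normalized
betweenness and the absolute log2 fold change of their strongest significant
feature — reproducing a centrality x fold-change scatter prioritization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import EdgeList, FeatureAnnotation


def build_graph(
    edges: EdgeList,
    nodes_of_interest: Iterable[str],
    min_score: float = 0.15,
) -> nx.Graph:
    """Induced subgraph on nodes_of_interest with edges of score >= min_score.

    Isolated nodes are retained.  Node symbols are matched case-insensitively
    (stored upper case).  Nodes and edges are inserted in sorted order so every
    downstream algorithm is deterministic.
    """
    if not 0 <= min_score <= 1:
        raise ValueError("min_score must lie in [0, 1]")
    nodes = sorted({str(n).upper() for n in nodes_of_interest})
    if not nodes:
        raise ValueError("nodes_of_interest is empty")
    node_set = set(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    t = edges.table
    keep = (
        t["node_a"].isin(node_set)
        & t["node_b"].isin(node_set)
        & (t["combined_score"] >= min_score)
    )
    for row in t[keep].sort_values(["node_a", "node_b"]).itertuples():
        g.add_edge(row.node_a, row.node_b, combined_score=row.combined_score)
    return g


def betweenness(graph: nx.Graph) -> pd.DataFrame:
    """Raw and normalized unweighted shortest-path betweenness per node.

    Raw counts each unordered node pair once; the normalized variant divides by
    (n-1)(n-2)/2.  Pairs in different components contribute nothing.
    """
    raw = nx.betweenness_centrality(graph, normalized=False, weight=None)
    n = graph.number_of_nodes()
    denom = (n - 1) * (n - 2) / 2.0 if n > 2 else np.nan
    rows = [
        {
            "node": node,
            "betweenness": raw[node],
            "betweenness_norm": raw[node] / denom if n > 2 else 0.0,
            "degree": graph.degree[node],
        }
        for node in sorted(graph.nodes)
    ]
    return pd.DataFrame(rows)


def cluster_communities(graph: nx.Graph) -> dict[str, int]:
    """Greedy modularity communities; isolated nodes become singletons.

    Community ids are contiguous from 0, assigned in order of (size descending,
    smallest member node) for determinism.
    """
    isolated = sorted(n for n in graph.nodes if graph.degree[n] == 0)
    core = graph.subgraph(n for n in graph.nodes if graph.degree[n] > 0)
    communities: list[frozenset] = []
    if core.number_of_edges() > 0:
        communities = [frozenset(c) for c in
                       nx.algorithms.community.greedy_modularity_communities(core)]
    communities += [frozenset([n]) for n in isolated]
    communities.sort(key=lambda c: (-len(c), min(c)))
    membership: dict[str, int] = {}
    for cid, members in enumerate(communities):
        for node in members:
            membership[node] = cid
    return membership


@dataclass
class PriorityResults:
    """Centrality x fold-change prioritization table."""

    table: pd.DataFrame  # node, betweenness, betweenness_norm, degree, community,
    #                       log2_fc, fc_source, priority_product, rank

    def summary(self) -> str:
        ranked = self.table.dropna(subset=["rank"]).sort_values("rank")
        top = ranked.head(5)
        lines = [
            f"Network prioritization: {len(self.table)} nodes, "
            f"{int(self.table['rank'].notna().sum())} ranked",
            "top nodes (betweenness_norm x |log2 FC|):",
        ]
        for row in top.itertuples():
            lines.append(
                f"  {int(row.rank):3d}. {row.node}  b={row.betweenness_norm:.4f} "
                f"log2FC={row.log2_fc:+.2f} product={row.priority_product:.4f}"
            )
        return "\n".join(lines)


class NetworkPrioritization:
    """Model object: build the graph and rank nodes by centrality x fold change.

    ``differential_tables`` maps a dataset kind ("phosphosite" / "protein") to a
    fitted differential table; phosphosite evidence is preferred and the
    protein-expression row is used only for nodes without a significant
    phosphosite.  Each node's fold change is the log2 ratio of its
    maximum-|log2 ratio| *passing* row for the chosen contrast.
    """

    def __init__(
        self,
        edges: EdgeList,
        differential_tables: Mapping[str, pd.DataFrame],
        annotations: Sequence[FeatureAnnotation],
        contrast: str,
        min_score: float = 0.15,
        nodes_of_interest: Optional[Iterable[str]] = None,
    ) -> None:
        self.edges = edges
        self.tables = dict(differential_tables)
        self.contrast = contrast
        self.min_score = min_score
        self.gene_of = {a.feature_id: a.gene_symbol for a in annotations}
        if nodes_of_interest is None:
            nodes_of_interest = self._significant_genes()
        self.nodes_of_interest = sorted({str(n).upper() for n in nodes_of_interest})

    def _significant_genes(self) -> set[str]:
        genes: set[str] = set()
        for table in self.tables.values():
            passed = table[table[f"{self.contrast}.passed"]]
            genes |= {
                self.gene_of[f].upper() for f in passed["feature_id"] if self.gene_of.get(f)
            }
        return genes

    def _node_fold_changes(self) -> dict[str, tuple[float, str]]:
        """gene -> (log2 fc of strongest passing row, source kind)."""
        best: dict[str, tuple[float, str]] = {}
        for kind in ("phosphosite", "protein"):  # phosphosite evidence preferred
            table = self.tables.get(kind)
            if table is None:
                continue
            passed = table[table[f"{self.contrast}.passed"]]
            deltas = passed[f"{self.contrast}.log2_ratio"]
            for fid, delta in zip(passed["feature_id"], deltas):
                gene = self.gene_of.get(fid, "").upper()
                if not gene:
                    continue
                if gene in best and best[gene][1] == "phosphosite" and kind == "protein":
                    continue
                if gene not in best or abs(delta) > abs(best[gene][0]):
                    best[gene] = (float(delta), kind)
        return best

    def fit(self) -> PriorityResults:
        graph = build_graph(self.edges, self.nodes_of_interest, self.min_score)
        stats = betweenness(graph).set_index("node")
        membership = cluster_communities(graph)
        fc = self._node_fold_changes()

        rows = []
        for node in stats.index:
            delta, source = fc.get(node, (np.nan, "absent"))
            product = (
                stats.loc[node, "betweenness_norm"] * abs(delta)
                if np.isfinite(delta)
                else np.nan
            )
            rows.append(
                {
                    "node": node,
                    "betweenness": stats.loc[node, "betweenness"],
                    "betweenness_norm": stats.loc[node, "betweenness_norm"],
                    "degree": stats.loc[node, "degree"],
                    "community": membership[node],
                    "log2_fc": delta,
                    "fc_source": source,
                    "priority_product": product,
                }
            )
        table = pd.DataFrame(rows)
        ranked = table[table["priority_product"].notna()].copy()
        ranked["abs_fc"] = ranked["log2_fc"].abs()
        ranked = ranked.sort_values(
            by=["priority_product", "abs_fc", "node"], ascending=[False, False, True],
            kind="stable",
        )
        rank = pd.Series(np.arange(1, len(ranked) + 1), index=ranked.index, dtype=float)
        table["rank"] = rank.reindex(table.index)
        self.graph_ = graph
        return PriorityResults(table=table.sort_values(
            by=["rank", "node"], na_position="last", kind="stable").reset_index(drop=True))


def prioritize(
    edges: EdgeList,
    differential_tables: Mapping[str, pd.DataFrame],
    annotations: Sequence[FeatureAnnotation],
    contrast: str,
    min_score: float = 0.15,
    nodes_of_interest: Optional[Iterable[str]] = None,
) -> PriorityResults:
    """Functional wrapper around :class:`NetworkPrioritization`."""
    return NetworkPrioritization(
        edges, differential_tables, annotations, contrast, min_score, nodes_of_interest
    ).fit()
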