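"""Reconstruction of a connecting "amplification pathway" from seed marker
genes over merged interaction networks.

Procedure: merge the source networks (node union; parallel edges collapsed,
conflicting signs marked ambiguous), link every pair of seed genes in the
same component by ALL shortest paths (unit edge weights, hop limit), take the
subgraph induced by the union of path nodes, then iteratively cut
loosely-connected branches (non-seed nodes of degree <= 1) until a fixed
point. Using all shortest paths rather than one arbitrary path removes
tie-breaking nondeterminism; seeds are never pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ReconstructedPathway",
    "merge_networks",
    "shortest_links",
    "prune_branches",
    "build_pathway",
    "render_pathway",
]


@dataclass
class ReconstructedPathway:
    """Seed/intermediary partition of the reconstructed subnetwork."""

    seed_nodes: set[str]
    intermediary_nodes: set[str]
    edges: list[tuple[str, str, int]]  # sorted; sign 0 = ambiguous
    unreachable_seeds: set[str]
    missing_seeds: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.seed_nodes | self.intermediary_nodes)

    def summary(self) -> dict:
        return {
            "n_seeds_found": len(self.seed_nodes),
            "n_intermediaries": len(self.intermediary_nodes),
            "n_edges": len(self.edges),
            "unreachable_seeds": sorted(self.unreachable_seeds),
            "missing_seeds": sorted(self.missing_seeds),
        }

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, sign in self.edges:
            g.add_edge(u, v, sign=sign)
        return g


def merge_networks(graphs: list[nx.Graph]) -> nx.Graph:
    """Node union of the source databases with parallel-edge collapsing.

    A repeated edge keeps every provenance tag; conflicting signs are stored
    as 0 (ambiguous — excluded from sign rendering but usable for paths).
    """
    merged = nx.Graph(name="merged")
    for graph in graphs:
        merged.add_nodes_from(graph.nodes)
        for u, v, data in graph.edges(data=True):
            sign = data.get("sign", 0)
            prov = tuple(data.get("provenance", (graph.graph.get("name", "?"),)))
            if merged.has_edge(u, v):
                old = merged[u][v]
                old["provenance"] = tuple(sorted(set(old["provenance"]) | set(prov)))
                if old["sign"] != sign:
                    old["sign"] = 0
            else:
                merged.add_edge(u, v, sign=sign, provenance=prov)
    return merged


def shortest_links(
    graph: nx.Graph, seeds: set[str], max_len: int = 4
) -> tuple[set[str], set[frozenset[str]], set[str], set[str]]:
    """Union of ALL shortest paths between seed pairs within ``max_len`` hops.

    Returns (path_nodes, path_edges, unreachable_seeds, missing_seeds).
    Seeds absent from the graph are reported, not fatal; a seed pair farther
    apart than ``max_len`` is left unlinked and both ends flagged unreachable
    unless linked through some other pair.
    """
    if max_len < 1:
        raise ValueError("max_len must be at least 1")
    missing = {s for s in seeds if s not in graph}
    present = sorted(seeds - missing)

    path_nodes: set[str] = set()
    path_edges: set[frozenset[str]] = set()
    linked: set[str] = set()
    for a, b in combinations(present, 2):
        # Dijkstra with unit weights degenerates to BFS; cutoff bounds the search
        try:
            dist = nx.shortest_path_length(graph, a, b)
        except nx.NetworkXNoPath:
            continue
        if dist > max_len:
            continue
        for path in nx.all_shortest_paths(graph, a, b):
            path_nodes.update(path)
            path_edges.update(frozenset(e) for e in zip(path, path[1:]))
        linked.update((a, b))
    unreachable = set(present) - linked
    if len(present) == 1:
        # a lone seed has no pair to link to but is retained
        path_nodes.update(present)
        unreachable = set()
    return path_nodes, path_edges, unreachable, missing


def prune_branches(subgraph: nx.Graph, seeds: set[str]) -> nx.Graph:
    """Iteratively delete non-seed nodes of degree <= 1 until a fixed point."""
    g = subgraph.copy()
    while True:
        dangling = [n for n in g.nodes if n not in seeds and g.degree(n) <= 1]
        if not dangling:
            return g
        g.remove_nodes_from(dangling)


def build_pathway(
    graph: nx.Graph,
    seeds: set[str],
    max_len: int = 4,
    induced: bool = False,
) -> ReconstructedPathway:
    """Full reconstruction: link seeds, restrict, prune, partition.

    By default the retained edges are exactly those lying on some shortest
    seed-pair path; ``induced=True`` instead keeps every merged-graph edge
    between retained nodes.
    """
    nodes, edges, unreachable, missing = shortest_links(graph, set(seeds), max_len)
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    if induced:
        sub.add_edges_from(
            (u, v, dict(d)) for u, v, d in graph.subgraph(nodes).edges(data=True)
        )
    else:
        for e in edges:
            u, v = sorted(e)
            sub.add_edge(u, v, **graph[u][v])
    pruned = prune_branches(sub, set(seeds))

    seed_nodes = {n for n in pruned.nodes if n in seeds}
    intermediaries = {n for n in pruned.nodes if n not in seeds}
    edge_list = sorted(
        (min(u, v), max(u, v), int(d.get("sign", 0))) for u, v, d in pruned.edges(data=True)
    )
    return ReconstructedPathway(
        seed_nodes=seed_nodes,
        intermediary_nodes=intermediaries,
        edges=edge_list,
        unreachable_seeds=unreachable,
        missing_seeds=missing,
    )


def render_pathway(
    pathway: ReconstructedPathway,
    cnr_by_group: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Node table with group-averaged log10 CNR attributes for export.

    For every node and sample group the attached attribute is the mean over
    samples of log10 CNR; nodes without expression keep a null attribute but
    remain in the table (a network node need not be measured on every chip).
    """
    rows = []
    for node in pathway.nodes:
        row: dict[str, object] = {
            "node": node,
            "role": "seed" if node in pathway.seed_nodes else "intermediary",
        }
        for group, cnr in cnr_by_group.items():
            if node in cnr.index:
                row[f"log10_cnr_{group}"] = float(np.log10(cnr.loc[node]).mean())
            else:
                row[f"log10_cnr_{group}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_pathway(pathway: ReconstructedPathway, prefix: str | Path) -> None:
    """SIF + node-role TSV export (sorted, deterministic)."""
    prefix = Path(prefix)
    reverse = {1: "activates", -1: "inhibits", 0: "interacts"}
    sif = [f"{u}\t{reverse[s]}\t{v}" for u, v, s in pathway.edges]
    prefix.with_suffix(".sif").write_text("\n".join(sif) + ("\n" if sif else ""), encoding="utf-8")
    roles = [
        f"{n}\t{'seed' if n in pathway.seed_nodes else 'intermediary'}"
        for n in pathway.nodes
    ]
    prefix.with_suffix(".nodes.tsv").write_text(
        "node\trole\n" + "\n".join(roles) + "\n", encoding="utf-8"
    )
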