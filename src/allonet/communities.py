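"""Hubs, k-cliques and clique-percolation communities.

A k-clique community is the union of k-cliques that can be chained through
adjacent cliques. Classical clique percolation joins cliques sharing k−1
nodes; the relaxed rule used here (the default) also joins cliques sharing
k−2 nodes, which merges more loosely coupled modules. Community stability
over a conformational ensemble is the fraction of snapshots in which every
edge of every member clique is present; communities intact in more than 75%
of snapshots count as dynamically stable.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import networkx as nx

from .structure_network import EnsembleGraphSet

__all__ = [
    "CliqueSet",
    "CommunitySet",
    "find_hubs",
    "enumerate_k_cliques",
    "clique_percolation_communities",
    "community_stability_filter",
]


@dataclasses.dataclass
class CliqueSet:
    """All k-cliques of a graph, each a sorted node tuple, no duplicates."""

    k: int
    cliques: list[tuple]


@dataclasses.dataclass
class CommunitySet:
    """Overlapping communities from clique percolation."""

    communities: list[frozenset]
    k: int
    rule: str  # "strict" (share k-1) | "relaxed" (share >= k-2)
    member_cliques: list[list[tuple]]
    stability: list[float] | None = None


def find_hubs(graph: nx.Graph, min_degree: int = 4) -> set:
    """Nodes with degree at least ``min_degree`` (default 4)."""
    return {n for n, d in graph.degree if d >= min_degree}


def enumerate_k_cliques(graph: nx.Graph, k: int) -> CliqueSet:
    """All complete subgraphs of exactly ``k`` nodes, each reported once in
    sorted node order."""
    if k < 2:
        raise ValueError("k must be >= 2")
    nodes = sorted(graph.nodes)
    adj = {u: set(graph.neighbors(u)) for u in nodes}
    cliques: list[tuple] = []

    def extend(clique: list, candidates: list) -> None:
        if len(clique) == k:
            cliques.append(tuple(clique))
            return
        for i, u in enumerate(candidates):
            new_cand = [v for v in candidates[i + 1 :] if v in adj[u]]
            if len(clique) + 1 + len(new_cand) < k:
                continue
            extend(clique + [u], new_cand)

    extend([], nodes)
    return CliqueSet(k, cliques)


def clique_percolation_communities(
    cliques: CliqueSet, rule: str = "relaxed"
) -> CommunitySet:
    """Communities = connected components of the clique-adjacency graph.

    ``rule="strict"``: two k-cliques are adjacent iff they share k−1 nodes
    (classical CPM). ``rule="relaxed"``: sharing k−1 or k−2 nodes suffices.
    A community's node set is the union of its member cliques.
    """
    if rule not in ("strict", "relaxed"):
        raise ValueError(f"unknown adjacency rule '{rule}'")
    k = cliques.k
    min_shared = k - 1 if rule == "strict" else max(k - 2, 1)
    cl = cliques.cliques
    meta = nx.Graph()
    meta.add_nodes_from(range(len(cl)))
    sets = [set(c) for c in cl]
    for a, b in combinations(range(len(cl)), 2):
        if len(sets[a] & sets[b]) >= min_shared:
            meta.add_edge(a, b)
    communities: list[frozenset] = []
    members: list[list[tuple]] = []
    for comp in nx.connected_components(meta):
        comp = sorted(comp)
        nodes = frozenset().union(*(sets[c] for c in comp))
        communities.append(nodes)
        members.append([cl[c] for c in comp])
    # deterministic output: sort by size descending then lexicographic nodes
    order = sorted(
        range(len(communities)),
        key=lambda i: (-len(communities[i]), sorted(communities[i])),
    )
    return CommunitySet(
        [communities[i] for i in order],
        k,
        rule,
        [members[i] for i in order],
    )


def _community_edges(member_cliques: list[tuple]) -> set[frozenset]:
    edges: set[frozenset] = set()
    for clique in member_cliques:
        for u, v in combinations(clique, 2):
            edges.add(frozenset((u, v)))
    return edges


def community_stability_filter(
    communities: CommunitySet,
    graph_set: EnsembleGraphSet,
    threshold: float = 0.75,
) -> CommunitySet:
    """Keep communities intact in strictly more than ``threshold`` of the
    snapshot graphs.

    A community is intact in a snapshot iff every edge of every member
    k-clique exists in that snapshot's graph. The surviving communities carry
    their stability fractions.
    """
    kept: list[frozenset] = []
    kept_members: list[list[tuple]] = []
    stability: list[float] = []
    n = len(graph_set.graphs)
    if n == 0:
        raise ValueError("empty graph set")
    for nodes, member_cliques in zip(communities.communities, communities.member_cliques):
        edges = _community_edges(member_cliques)
        intact = sum(
            1
            for g in graph_set.graphs
            if all(g.has_edge(*tuple(e)) for e in edges)
        )
        frac = intact / n
        if frac > threshold:
            kept.append(nodes)
            kept_members.append(member_cliques)
            stability.append(frac)
    return CommunitySet(kept, communities.k, communities.rule, kept_members, stability)
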