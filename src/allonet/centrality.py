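"""Dynamics-weighted shortest-path centrality.

Edges of the residue interaction network are weighted by the dynamic
information flow between the residues they join, w_ij = −log|C_ij| with C
the cross-correlation of positional fluctuations: strongly correlated pairs
are "close". All-pairs shortest-path distances come from the Floyd–Warshall
algorithm; shortest-path multiplicities g_jk and pass-through counts g_jk(i)
are accumulated on the shortest-path DAG with an explicit floating-point tie
tolerance. The normalized betweenness of node i is

    C_b(i) = [ Σ_{j<k, j≠i≠k} g_jk(i)/g_jk ] / [ (N−1)(N−2)/2 ]

with N the size of i's connected component, so 0 ≤ C_b ≤ 1 and leaves score
exactly 0.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import networkx as nx
from scipy.sparse.csgraph import floyd_warshall

from .ensemble_dynamics import CrossCorrelationMatrix
from .structure_io import ResidueKey
from .structure_network import CoverageError, EnsembleGraphSet

__all__ = [
    "WeightedGraph",
    "PathCounts",
    "CentralityProfile",
    "assign_edge_weights",
    "shortest_path_counts",
    "betweenness_profile",
    "betweenness_centrality",
    "ensemble_centrality",
    "centrality_distribution",
    "cluster_average_centrality",
]

#: relative tolerance under which two path lengths count as equal
TIE_RTOL = 1e-9


@dataclasses.dataclass
class WeightedGraph:
    """Residue graph with information-flow edge weights w = −log|C|."""

    graph: nx.Graph
    floor: float
    c_min: float | None


@dataclasses.dataclass
class PathCounts:
    """All-pairs shortest-path data over a fixed node order."""

    nodes: list
    dist: np.ndarray  # (n, n), np.inf for unreachable
    sigma: np.ndarray  # (n, n) shortest-path multiplicities
    through: np.ndarray  # (n, n, n): through[i, j, k] = g_jk(i)


@dataclasses.dataclass
class CentralityProfile:
    """Per-residue normalized betweenness in [0, 1]."""

    values: dict
    component_sizes: dict

    def as_array(self, order: Sequence | None = None) -> np.ndarray:
        keys = list(order) if order is not None else list(self.values)
        return np.array([self.values[k] for k in keys], dtype=float)


def assign_edge_weights(
    graph: nx.Graph,
    correlations: CrossCorrelationMatrix | Mapping,
    floor: float = 1e-8,
    c_min: float | None = 0.5,
    signed: bool = False,
) -> WeightedGraph:
    """Weight graph edges by w = −log|C| and drop weakly correlated edges.

    ``c_min`` (default 0.5, the correlated-intermediate band) removes edges
    whose correlation magnitude — or signed value if ``signed`` — is below
    the threshold before any path analysis. ``floor`` caps the weight of
    near-zero correlations at −log(floor).
    """
    if isinstance(correlations, CrossCorrelationMatrix):
        index = {k: i for i, k in enumerate(correlations.residues)}

        def get_c(u, v):
            try:
                return float(correlations.matrix[index[u], index[v]])
            except KeyError:
                raise CoverageError(f"no correlation entry for ({u}, {v})")
    else:
        def get_c(u, v):
            try:
                return float(correlations[(u, v)] if (u, v) in correlations else correlations[(v, u)])
            except KeyError:
                raise CoverageError(f"no correlation entry for ({u}, {v})")

    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        c = get_c(u, v)
        gate = c if signed else abs(c)
        if c_min is not None and gate < c_min:
            continue
        w = -np.log(max(abs(c), floor))
        out.add_edge(u, v, weight=float(w), correlation=c, **{
            k: val for k, val in data.items() if k not in ("weight", "correlation")
        })
    return WeightedGraph(out, floor, c_min)


def shortest_path_counts(graph: WeightedGraph | nx.Graph) -> PathCounts:
    """All-pairs shortest-path distances, multiplicities and pass-through
    counts on a non-negatively weighted graph.

    Distances are computed with Floyd–Warshall; multiplicities are then
    accumulated per source over nodes in order of increasing distance, and
    g_jk(i) = σ(j,i)·σ(i,k) wherever d(j,i)+d(i,k) equals d(j,k) within the
    tie tolerance.
    """
    g = graph.graph if isinstance(graph, WeightedGraph) else graph
    nodes = list(g.nodes)
    n = len(nodes)
    index = {u: i for i, u in enumerate(nodes)}
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    for u, v, data in g.edges(data=True):
        weight = float(data.get("weight", 1.0))
        if weight < 0:
            raise ValueError("negative edge weight")
        i, j = index[u], index[v]
        w[i, j] = w[j, i] = min(w[i, j], weight)

    dist = floyd_warshall(w, directed=False)

    def close(a: np.ndarray, b) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.abs(a - b) <= TIE_RTOL * np.maximum(
                1.0, np.maximum(np.abs(a), np.abs(b))
            )

    # multiplicities per source via DP over nodes sorted by distance
    sigma = np.zeros((n, n))
    finite_edge = np.isfinite(w) & ~np.eye(n, dtype=bool)
    for s in range(n):
        order = np.argsort(dist[s], kind="stable")
        sigma[s, s] = 1.0
        for v in order:
            if v == s or not np.isfinite(dist[s, v]):
                continue
            preds = np.flatnonzero(
                finite_edge[:, v] & close(dist[s] + w[:, v], dist[s, v])
            )
            sigma[s, v] = sigma[s, preds].sum()

    # pass-through counts
    through = np.zeros((n, n, n))
    for i in range(n):
        dji = dist[:, i][:, None]
        dik = dist[i, :][None, :]
        on_path = close(dji + dik, dist) & np.isfinite(dist)
        gi = np.outer(sigma[:, i], sigma[i, :]) * on_path
        gi[i, :] = 0.0
        gi[:, i] = 0.0
        np.fill_diagonal(gi, 0.0)
        through[i] = gi

    return PathCounts(nodes, dist, sigma, through)


def betweenness_profile(counts: PathCounts) -> CentralityProfile:
    """Normalized betweenness from precomputed path counts (see module
    docstring). Components of fewer than 3 nodes score 0."""
    n = len(counts.nodes)
    reachable = np.isfinite(counts.dist)
    comp_size = reachable.sum(axis=1)  # includes self
    values: dict = {}
    comp_sizes: dict = {}
    for i in range(n):
        node = counts.nodes[i]
        big_n = int(comp_size[i])
        comp_sizes[node] = big_n
        if big_n < 3:
            values[node] = 0.0
            continue
        gi = counts.through[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(counts.sigma > 0, gi / np.where(counts.sigma > 0, counts.sigma, 1.0), 0.0)
        # unordered pairs j<k, both ≠ i
        total = (np.triu(frac, k=1)).sum()
        norm = (big_n - 1) * (big_n - 2) / 2.0
        values[node] = float(total / norm)
    return CentralityProfile(values, comp_sizes)


def betweenness_centrality(
    graph: WeightedGraph | nx.Graph,
) -> CentralityProfile:
    """Convenience wrapper: path counting + normalized betweenness."""
    return betweenness_profile(shortest_path_counts(graph))


def ensemble_centrality(
    graph_set: EnsembleGraphSet,
    correlations: CrossCorrelationMatrix | Mapping | None = None,
    floor: float = 1e-8,
    c_min: float | None = 0.5,
) -> CentralityProfile:
    """Ensemble-averaged betweenness: the per-residue mean of per-snapshot
    normalized betweenness. Unweighted snapshot graphs are used when no
    correlation matrix is given."""
    if not graph_set.graphs:
        raise ValueError("empty graph set")
    sums: dict = {}
    comp: dict = {}
    for g in graph_set.graphs:
        if correlations is not None:
            wg = assign_edge_weights(g, correlations, floor=floor, c_min=c_min)
            prof = betweenness_centrality(wg)
        else:
            prof = betweenness_centrality(g)
        for k, v in prof.values.items():
            sums[k] = sums.get(k, 0.0) + v
            comp[k] = max(comp.get(k, 0), prof.component_sizes[k])
    n = len(graph_set.graphs)
    return CentralityProfile({k: v / n for k, v in sums.items()}, comp)


def centrality_distribution(
    profile: CentralityProfile,
    bins: int = 25,
    tail_quantile: float = 0.9,
) -> dict:
    """Probability distribution of centrality values.

    Returns bin edges, normalized masses (summing to 1), and the tail mass
    of values strictly above the given quantile of the profile.
    """
    vals = np.array(list(profile.values.values()), dtype=float)
    if vals.size == 0:
        raise ValueError("empty profile")
    counts, edges = np.histogram(vals, bins=bins)
    masses = counts / counts.sum()
    q = float(np.quantile(vals, tail_quantile))
    tail_mass = float((vals > q).sum() / vals.size)
    return {
        "bin_edges": edges,
        "masses": masses,
        "tail_quantile": tail_quantile,
        "tail_value": q,
        "tail_mass": tail_mass,
    }


def cluster_average_centrality(
    profile: CentralityProfile,
    clusters: Mapping[str, Sequence],
) -> dict[str, float]:
    """Arithmetic mean centrality per named residue cluster (e.g. mutation
    clusters); unknown residues or empty clusters are validation errors."""
    out: dict[str, float] = {}
    for name, members in clusters.items():
        members = list(members)
        if not members:
            raise ValueError(f"cluster '{name}' is empty")
        vals = []
        for m in members:
            if m not in profile.values:
                raise ValueError(f"cluster '{name}': unknown residue {m}")
            vals.append(profile.values[m])
        out[name] = float(np.mean(vals))
    return out
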