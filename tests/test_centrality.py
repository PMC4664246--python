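"""Dynamics-weighted betweenness: weights, path counting, normalization.

The oracle is an exhaustive simple-path enumerator (conftest), independent
of the Floyd–Warshall + DAG-counting production path; networkx's Brandes
betweenness is a second cross-check on connected unit-weight graphs.
"""

import math

import networkx as nx
import numpy as np
import pytest

from allonet import centrality as cent
from allonet.structure_network import EnsembleGraphSet
from conftest import brute_force_betweenness


def _unit_graph(edges):
    g = nx.Graph()
    g.add_edges_from((u, v, {"weight": 1.0}) for u, v in edges)
    return g


# -- edge weights -----------------------------------------------------------


def test_edge_weight_values():
    g = nx.Graph([(1, 2), (2, 3), (1, 3)])
    corr = {(1, 2): 1.0, (2, 3): 0.5, (1, 3): 0.0}
    wg = cent.assign_edge_weights(g, corr, floor=1e-8, c_min=None)
    assert wg.graph[1][2]["weight"] == pytest.approx(0.0)
    assert wg.graph[2][3]["weight"] == pytest.approx(math.log(2), abs=1e-12)
    assert wg.graph[1][3]["weight"] == pytest.approx(-math.log(1e-8))


def test_correlation_filter_removes_weak_edges():
    g = nx.Graph([(1, 2), (2, 3), (1, 3)])
    corr = {(1, 2): 0.9, (2, 3): 0.4, (1, 3): -0.8}
    wg = cent.assign_edge_weights(g, corr, c_min=0.5)
    assert set(wg.graph.edges) == {(1, 2), (1, 3)}  # |−0.8| passes, 0.4 fails
    wg_signed = cent.assign_edge_weights(g, corr, c_min=0.5, signed=True)
    assert set(wg_signed.graph.edges) == {(1, 2)}


def test_missing_correlation_is_coverage_error():
    from allonet.structure_network import CoverageError

    g = nx.Graph([(1, 2)])
    with pytest.raises(CoverageError):
        cent.assign_edge_weights(g, {}, c_min=None)


# -- path counting ----------------------------------------------------------


def test_path_graph_counts():
    counts = cent.shortest_path_counts(_unit_graph([(1, 2), (2, 3)]))
    i = {u: n for n, u in enumerate(counts.nodes)}
    assert counts.dist[i[1], i[3]] == pytest.approx(2.0)
    assert counts.sigma[i[1], i[3]] == 1
    assert counts.through[i[2], i[1], i[3]] == 1


def test_four_cycle_multiplicity():
    counts = cent.shortest_path_counts(_unit_graph([(1, 2), (2, 3), (3, 4), (4, 1)]))
    i = {u: n for n, u in enumerate(counts.nodes)}
    assert counts.sigma[i[1], i[3]] == 2
    assert counts.sigma[i[2], i[4]] == 2


def test_weighted_triangle_two_hop_beats_direct():
    g = nx.Graph()
    g.add_edge(1, 3, weight=0.7)
    g.add_edge(1, 2, weight=0.3)
    g.add_edge(2, 3, weight=0.3)
    counts = cent.shortest_path_counts(g)
    i = {u: n for n, u in enumerate(counts.nodes)}
    assert counts.dist[i[1], i[3]] == pytest.approx(0.6)
    assert counts.through[i[2], i[1], i[3]] == 1


# -- betweenness ------------------------------------------------------------


def test_star_center_and_leaves():
    prof = cent.betweenness_centrality(_unit_graph([(0, k) for k in (1, 2, 3, 4)]))
    assert prof.values[0] == pytest.approx(1.0)
    for leaf in (1, 2, 3, 4):
        assert prof.values[leaf] == 0.0


def test_path_of_five_middle():
    prof = cent.betweenness_centrality(
        _unit_graph([(1, 2), (2, 3), (3, 4), (4, 5)])
    )
    assert prof.values[3] == pytest.approx(4 / 6)
    assert prof.values[2] == pytest.approx(3 / 6)
    assert prof.values[1] == 0.0


@pytest.mark.parametrize("weighted", [False, True])
def test_oracle_equivalence_random_graphs(weighted):
    rng = np.random.default_rng(17 if weighted else 23)
    for trial in range(60):
        n = int(rng.integers(4, 10))
        p = 0.2 + 0.3 * rng.random()
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 2.0)) if weighted else 1.0
        prof = cent.betweenness_centrality(g)
        oracle = brute_force_betweenness(g)
        for u in g.nodes:
            assert prof.values[u] == pytest.approx(oracle[u], abs=1e-9)


def test_matches_networkx_on_connected_unit_graphs():
    rng = np.random.default_rng(5)
    done = 0
    while done < 20:
        g = nx.gnp_random_graph(9, 0.35, seed=int(rng.integers(1 << 30)))
        if not nx.is_connected(g):
            continue
        done += 1
        prof = cent.betweenness_centrality(g)
        ref = nx.betweenness_centrality(g, normalized=True)
        for u in g.nodes:
            assert prof.values[u] == pytest.approx(ref[u], abs=1e-9)


def test_disconnected_normalization_uses_component_size():
    # two components: a path of 3 and a path of 5
    g = _unit_graph([(1, 2), (2, 3), (10, 11), (11, 12), (12, 13), (13, 14)])
    prof = cent.betweenness_centrality(g)
    assert prof.values[2] == pytest.approx(1.0)  # middle of 3-path
    assert prof.values[12] == pytest.approx(4 / 6)
    assert prof.component_sizes[2] == 3
    assert prof.component_sizes[12] == 5


def test_permutation_invariance():
    rng = np.random.default_rng(7)
    g = nx.gnp_random_graph(8, 0.4, seed=3)
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.5, 1.5))
    prof = cent.betweenness_centrality(g)
    mapping = dict(zip(g.nodes, rng.permutation(list(g.nodes))))
    g2 = nx.relabel_nodes(g, mapping)
    prof2 = cent.betweenness_centrality(g2)
    for u in g.nodes:
        assert prof.values[u] == pytest.approx(prof2.values[mapping[u]], abs=1e-12)


def test_small_component_scores_zero():
    prof = cent.betweenness_centrality(_unit_graph([(1, 2)]))
    assert prof.values[1] == 0.0 and prof.values[2] == 0.0


# -- ensemble averaging and summaries ---------------------------------------


def _graph_set(graphs):
    return EnsembleGraphSet(graphs, {}, len(graphs))


def test_ensemble_centrality_is_mean_of_snapshots():
    g_star = _unit_graph([(0, k) for k in (1, 2, 3, 4)])
    g_path = _unit_graph([(1, 2), (2, 0), (0, 3), (3, 4)])
    p_star = cent.betweenness_centrality(g_star).values
    p_path = cent.betweenness_centrality(g_path).values
    prof = cent.ensemble_centrality(_graph_set([g_star, g_path]))
    for u in p_star:
        assert prof.values[u] == pytest.approx((p_star[u] + p_path[u]) / 2)


def test_ensemble_centrality_identical_graphs():
    g = _unit_graph([(1, 2), (2, 3), (3, 4)])
    single = cent.betweenness_centrality(g).values
    prof = cent.ensemble_centrality(_graph_set([g, g, g]))
    assert prof.values == pytest.approx(single)


def test_centrality_distribution_masses():
    prof = cent.betweenness_centrality(_unit_graph([(0, k) for k in (1, 2, 3, 4)]))
    dist = cent.centrality_distribution(prof, bins=5)
    assert dist["masses"].sum() == pytest.approx(1.0)
    occupied = dist["masses"][dist["masses"] > 0]
    assert sorted(occupied) == pytest.approx([1 / 5, 4 / 5])


def test_cluster_average_centrality():
    prof = cent.CentralityProfile({"a": 0.2, "b": 0.4, "c": 0.9}, {"a": 3, "b": 3, "c": 3})
    means = cent.cluster_average_centrality(prof, {"x": ["a", "b"], "y": ["c"]})
    assert means["x"] == pytest.approx(0.3)
    assert means["y"] == pytest.approx(0.9)
    with pytest.raises(ValueError):
        cent.cluster_average_centrality(prof, {"bad": ["zz"]})
    with pytest.raises(ValueError):
        cent.cluster_average_centrality(prof, {"empty": []})
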