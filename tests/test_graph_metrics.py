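"""Graph statistics against independent brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from coremetnet.data_model import DegreeDistribution, MetabolicGraph
from coremetnet.graph_metrics import (
    compare_connectivities,
    compute_metrics,
    degree_distribution,
    fit_power_law_tail,
)

# ---------------------------------------------------------------------------
# independent oracles (pure-python, no shared code with the implementation)
# ---------------------------------------------------------------------------

def bfs_lengths(adj, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def oracle_path_stats(graph: MetabolicGraph):
    """(diameter, avg finite path length over all unordered pairs)."""
    adj = {u: set(graph.graph[u]) for u in graph.graph}
    nodes = list(adj)
    n = len(nodes)
    diameter = 0
    total = 0
    for u in nodes:
        for v, d in bfs_lengths(adj, u).items():
            if v != u:
                total += d
                diameter = max(diameter, d)
    n_pairs = n * (n - 1) // 2
    return diameter, (total / 2) / n_pairs if n_pairs else 0.0


def oracle_transitivity(graph: MetabolicGraph):
    """3 * triangles / connected triples, by exhaustive triple enumeration."""
    adj = {u: set(graph.graph[u]) for u in graph.graph}
    triangles = 0
    triples = 0
    for a, b, c in itertools.combinations(adj, 3):
        edges = (b in adj[a]) + (c in adj[a]) + (c in adj[b])
        if edges == 3:
            triangles += 1
            triples += 3
        elif edges == 2:
            triples += 1
    return 3 * triangles / triples if triples else 0.0


def oracle_isolated_edges(graph: MetabolicGraph):
    adj = {u: set(graph.graph[u]) for u in graph.graph}
    count = 0
    for u in adj:
        nbrs = adj[u]
        if len(nbrs) == 1:
            (v,) = nbrs
            if len(adj[v]) == 1 and u < v:
                count += 1
    return count


def random_graph(rng):
    n = int(rng.integers(4, 61))
    p = rng.uniform(0.02, 0.25)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g.remove_nodes_from([u for u, d in list(g.degree()) if d == 0])
    return MetabolicGraph(nx.relabel_nodes(g, {u: f"C{u}" for u in g.nodes}))


# ---------------------------------------------------------------------------
# compute_metrics
# ---------------------------------------------------------------------------

class TestComputeMetrics:
    def test_triangle(self):
        m = compute_metrics(MetabolicGraph.from_edges([("A", "B"), ("B", "C"), ("C", "A")]))
        assert m.density == 1.0
        assert m.avg_connectivity == 2.0
        assert m.diameter == 1
        assert m.global_clustering == 1.0
        assert m.isolated_edges == 0

    def test_four_node_path(self):
        m = compute_metrics(
            MetabolicGraph.from_edges([("A", "B"), ("B", "C"), ("C", "D")])
        )
        assert m.diameter == 3
        assert m.global_clustering == 0.0
        assert m.max_connectivity == 2

    def test_k4_minus_edge_transitivity(self):
        g = nx.complete_graph(4)
        g.remove_edge(0, 1)
        m = compute_metrics(MetabolicGraph(nx.relabel_nodes(g, str)))
        assert m.global_clustering == pytest.approx(0.75)

    def test_reference_scale_arithmetic_identities(self):
        # at the published reference scale N=876, E=1184 the identities
        # 2E/(N(N-1)) and 2E/N give 0.0031 and 2.7 to printed precision
        g = MetabolicGraph(nx.gnm_random_graph(876, 1184, seed=0))
        m = compute_metrics(g)
        assert m.density == pytest.approx(2 * 1184 / (876 * 875))
        assert round(m.density, 4) == 0.0031
        assert round(m.avg_connectivity, 1) == 2.7

    def test_single_node_density_missing(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.remove_node("B")
        m = compute_metrics(MetabolicGraph(g))
        assert m.density is None

    def test_oracle_equivalence_on_random_graphs(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            graph = random_graph(rng)
            if graph.n_nodes < 2:
                continue
            m = compute_metrics(graph)
            diam, apl = oracle_path_stats(graph)
            assert m.diameter == diam
            assert m.avg_path_length == pytest.approx(apl)
            assert m.global_clustering == pytest.approx(oracle_transitivity(graph))
            assert m.isolated_edges == oracle_isolated_edges(graph)
            assert m.avg_path_length <= m.diameter

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        graph = random_graph(rng)
        perm = dict(zip(graph.graph.nodes,
                        rng.permutation(list(graph.graph.nodes))))
        relabeled = MetabolicGraph(nx.relabel_nodes(graph.graph, perm))
        assert compute_metrics(graph) == compute_metrics(relabeled)

    def test_average_clustering_convention_available(self):
        g = MetabolicGraph.from_edges(
            [("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")]
        )
        trans = compute_metrics(g, clustering="transitivity").global_clustering
        avg = compute_metrics(g, clustering="average").global_clustering
        assert trans == pytest.approx(3 * 1 / 5)
        assert avg == pytest.approx((1 + 1 + 1 / 3 + 0) / 4)


# ---------------------------------------------------------------------------
# degree distributions & power-law tails
# ---------------------------------------------------------------------------

class TestDegreeDistribution:
    def test_star_and_triangle(self):
        star = MetabolicGraph.from_edges([("H", "A"), ("H", "B"), ("H", "C")])
        assert degree_distribution(star).counts == {1: 3, 3: 1}
        tri = MetabolicGraph.from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        assert degree_distribution(tri).counts == {2: 3}

    def test_matches_per_node_tally_on_reference(self, reference_graph):
        tally = {}
        for node in reference_graph.graph:
            k = len(list(reference_graph.graph[node]))
            tally[k] = tally.get(k, 0) + 1
        dist = degree_distribution(reference_graph)
        assert dist.counts == tally
        assert dist.n_nodes == reference_graph.n_nodes


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        counts = {k: round(1000 * k**-2.0) for k in range(2, 11)}
        fit = fit_power_law_tail(DegreeDistribution(counts), k_min=2)
        assert fit.slope == pytest.approx(-2.0, abs=0.05)
        assert fit.r_squared > 0.99

    def test_uniform_counts_flat(self):
        counts = {k: 50 for k in range(2, 11)}
        fit = fit_power_law_tail(DegreeDistribution(counts), k_min=2)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_thin_tail_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_power_law_tail(DegreeDistribution({1: 10, 2: 5}), k_min=2)

    def test_degree_one_excluded_by_default_k_min(self):
        counts = {1: 10**6, **{k: round(1000 * k**-2.0) for k in range(2, 11)}}
        fit = fit_power_law_tail(DegreeDistribution(counts))
        assert fit.k_min == 2
        assert fit.slope == pytest.approx(-2.0, abs=0.05)


# ---------------------------------------------------------------------------
# connectivity comparison
# ---------------------------------------------------------------------------

class TestCompareConnectivities:
    def test_identical_graphs(self):
        g = MetabolicGraph.from_edges([("A", "B"), ("B", "C")])
        assert all(da == db for _, da, db in compare_connectivities(g, g))

    def test_absent_compound_scores_zero(self):
        star = MetabolicGraph.from_edges(
            [("A", "X1"), ("A", "X2"), ("A", "X3"), ("A", "X4")]
        )
        other = MetabolicGraph.from_edges([("X1", "X2")])
        rows = dict((c, (a, b)) for c, a, b in compare_connectivities(star, other))
        assert rows["A"] == (4, 0)

    def test_brute_force_oracle_on_random_pair(self):
        rng = np.random.default_rng(99)
        ga, gb = random_graph(rng), random_graph(rng)
        rows = compare_connectivities(ga, gb)
        assert {c for c, _, _ in rows} == ga.nodes | gb.nodes
        for c, da, db in rows:
            assert da == (ga.graph.degree(c) if c in ga.graph else 0)
            assert db == (gb.graph.degree(c) if c in gb.graph else 0)
        diffs = [da - db for _, da, db in rows]
        assert diffs == sorted(diffs, reverse=True)
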