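"""Whole-graph statistics, degree distributions and power-law tail fits.

Conventions for fragmented graphs (the organism networks fall into several
components) are explicit rather than implicit:

* ``diameter`` is the maximum *finite* shortest-path length over all node
  pairs — never infinite for a disconnected graph.
* ``avg_path_length`` sums finite shortest-path lengths over unordered
  pairs and divides by N(N-1)/2, so disconnected pairs contribute zero to
  the numerator but remain in the denominator.  This makes the statistic
  shrink as a graph fragments, which is the behaviour the comparative
  analysis relies on.
* ``global_clustering`` defaults to transitivity (3 x triangles / connected
  triples); mean local clustering is available via ``clustering="average"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as sps

from coremetnet.data_model import DegreeDistribution, GraphMetrics, MetabolicGraph


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares line on (log10 k, log10 count) for the degree tail."""

    slope: float
    intercept: float
    r_squared: float
    k_min: int


def compute_metrics(graph: MetabolicGraph, clustering: str = "transitivity") -> GraphMetrics:
    """Compute the standard statistics panel for one graph.

    ``density = 2E/(N(N-1))`` and ``avg_connectivity = 2E/N``; density is
    reported as missing (``None``) when N < 2.  See the module docstring
    for the path-length and clustering conventions.
    """
    g = graph.graph
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        return GraphMetrics(0, 0, None, 0.0, 0, 0.0, 0, 0.0, 0)

    density = 2.0 * m / (n * (n - 1)) if n >= 2 else None
    degrees = [d for _, d in g.degree()]
    avg_connectivity = 2.0 * m / n
    max_connectivity = max(degrees)

    # one BFS per node; finite pairs only
    diameter = 0
    finite_sum = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        finite_sum += sum(lengths.values())  # self-distance 0 contributes nothing
        ecc = max(lengths.values())
        if ecc > diameter:
            diameter = ecc
    n_pairs = n * (n - 1) // 2
    avg_path_length = (finite_sum / 2) / n_pairs if n_pairs else 0.0

    if clustering == "transitivity":
        global_clustering = nx.transitivity(g)
    elif clustering == "average":
        global_clustering = nx.average_clustering(g)
    else:
        raise ValueError(
            f"unknown clustering convention {clustering!r}; "
            "expected 'transitivity' or 'average'"
        )

    isolated = sum(
        1 for comp in nx.connected_components(g) if len(comp) == 2
    )
    return GraphMetrics(
        n_nodes=n,
        n_edges=m,
        density=density,
        avg_connectivity=avg_connectivity,
        max_connectivity=max_connectivity,
        avg_path_length=avg_path_length,
        diameter=diameter,
        global_clustering=float(global_clustering),
        isolated_edges=isolated,
    )


def degree_distribution(graph: MetabolicGraph) -> DegreeDistribution:
    """Frequency distribution of node degrees (post-construction: k >= 1)."""
    counts: dict[int, int] = {}
    for _, d in graph.graph.degree():
        counts[d] = counts.get(d, 0) + 1
    return DegreeDistribution(counts=counts)


def fit_power_law_tail(dist: DegreeDistribution, k_min: int = 2) -> PowerLawFit:
    """Fit log10(count) ~ log10(k) for degrees k >= k_min.

    Degree-1 nodes are excluded by the default ``k_min=2``: the networks are
    scale-free only once dead-ended metabolites are ignored, and the same
    exclusion is applied to every graph being compared.  Requires at least
    three distinct supported degrees in the tail.
    """
    points = [(k, c) for k, c in dist.items() if k >= k_min and c > 0]
    if len(points) < 3:
        raise ValueError(
            f"power-law tail fit needs >= 3 distinct degrees >= {k_min}; "
            f"got {len(points)}"
        )
    log_k = np.log10([k for k, _ in points])
    log_c = np.log10([c for _, c in points])
    fit = sps.linregress(log_k, log_c)
    return PowerLawFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        k_min=k_min,
    )


def compare_connectivities(
    graph_a: MetabolicGraph, graph_b: MetabolicGraph
) -> list[tuple[str, int, int]]:
    """Per-compound degree in two graphs (0 when absent).

    One row per compound in the union of node sets, sorted by decreasing
    ``degree_in_a - degree_in_b`` so that compounds enriched in the first
    graph surface at the top (ties broken alphabetically).
    """
    rows = [
        (
            cid,
            graph_a.graph.degree(cid) if cid in graph_a.graph else 0,
            graph_b.graph.degree(cid) if cid in graph_b.graph else 0,
        )
        for cid in graph_a.nodes | graph_b.nodes
    ]
    rows.sort(key=lambda r: (-(r[1] - r[2]), r[0]))
    return rows


__all__ = [
    "PowerLawFit",
    "compute_metrics",
    "degree_distribution",
    "fit_power_law_tail",
    "compare_connectivities",
]
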