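"""Random edge-deletion null model ("shrinkage").

Natural reductive evolution is contrasted with a negative control: edges
are removed from the reference network uniformly at random, without
replacement, until a target edge count is reached (mirroring how parasite
networks match the reference in diameter while random deletion fragments
the graph).  Nodes stranded at degree 0 are dropped; isolated edges are
retained and counted.  The "size" being targeted is the edge count — node
loss is passive.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev

import numpy as np

from coremetnet.data_model import DegreeDistribution, GraphMetrics, MetabolicGraph
from coremetnet.graph_metrics import compute_metrics, degree_distribution


def _child_rng(seed: int, replicate: int) -> np.random.Generator:
    # documented splitting rule: replicate r draws from SeedSequence([seed, r])
    return np.random.default_rng(np.random.SeedSequence([seed, replicate]))


@dataclass(frozen=True)
class ShrinkageEnsemble:
    """Replicate random shrinkages of one source graph.

    ``summary`` maps every :class:`GraphMetrics` field to its ensemble mean
    and SD (SD is ``None`` for a single replicate); ``pooled_degree_counts``
    sums degree counts over replicates.
    """

    n_replicates: int
    target_edges: int
    seed: int
    per_replicate: list[GraphMetrics]
    summary: dict[str, dict[str, float | None]]
    pooled_degree_counts: dict[int, int]

    @property
    def pooled_degree_distribution(self) -> DegreeDistribution:
        return DegreeDistribution(counts=self.pooled_degree_counts)


def shrink_once(
    graph: MetabolicGraph, target_edges: int, seed: int
) -> MetabolicGraph:
    """Remove uniformly random edges until exactly ``target_edges`` remain.

    Deterministic for fixed (graph, target, seed).  Degree-0 nodes are
    dropped from the result.
    """
    m = graph.n_edges
    if not 0 <= target_edges <= m:
        raise ValueError(
            f"target_edges={target_edges} outside [0, {m}] for "
            f"graph {graph.label!r}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    edges = sorted(tuple(sorted(e)) for e in graph.graph.edges)
    doomed = rng.choice(len(edges), size=m - target_edges, replace=False)
    g = graph.graph.copy()
    g.remove_edges_from(edges[i] for i in doomed)
    g.remove_nodes_from([node for node, deg in list(g.degree()) if deg == 0])
    return MetabolicGraph(g, label=f"{graph.label}|shrunk{target_edges}")


def shrink_ensemble(
    graph: MetabolicGraph,
    target_edges: int,
    n_replicates: int,
    seed: int,
) -> ShrinkageEnsemble:
    """Replicate :func:`shrink_once` with deterministic per-replicate seeds.

    Replicate ``r`` uses the child stream ``SeedSequence([seed, r])``, so an
    ensemble can be extended without disturbing earlier replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    per_replicate: list[GraphMetrics] = []
    pooled: dict[int, int] = {}
    m = graph.n_edges
    if not 0 <= target_edges <= m:
        raise ValueError(f"target_edges={target_edges} outside [0, {m}]")
    edges = sorted(tuple(sorted(e)) for e in graph.graph.edges)
    for r in range(n_replicates):
        rng = _child_rng(seed, r)
        doomed = rng.choice(len(edges), size=m - target_edges, replace=False)
        g = graph.graph.copy()
        g.remove_edges_from(edges[i] for i in doomed)
        g.remove_nodes_from([n for n, d in list(g.degree()) if d == 0])
        shrunk = MetabolicGraph(g)
        per_replicate.append(compute_metrics(shrunk))
        for k, c in degree_distribution(shrunk).counts.items():
            pooled[k] = pooled.get(k, 0) + c

    summary: dict[str, dict[str, float | None]] = {}
    for name in GraphMetrics.field_names():
        values = [getattr(met, name) for met in per_replicate]
        values = [float(v) for v in values if v is not None]
        summary[name] = {
            "mean": mean(values) if values else None,
            "sd": stdev(values) if len(values) > 1 else None,
        }
    return ShrinkageEnsemble(
        n_replicates=n_replicates,
        target_edges=target_edges,
        seed=seed,
        per_replicate=per_replicate,
        summary=summary,
        pooled_degree_counts=pooled,
    )


__all__ = ["ShrinkageEnsemble", "shrink_once", "shrink_ensemble"]
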