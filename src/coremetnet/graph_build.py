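"""Reconstruction of core metabolic graphs from reaction tables.

Two metabolites are connected only when carbon atoms are transferred
between them, i.e. when the reaction's curated main (educt, product) pairs
say so — phosphate/electron exchange never creates an edge, and pairs that
touch a currency metabolite are dropped so ATP, NADH etc. cannot become
hubs.  Organism graphs arise by selecting the reactions whose EC numbers
intersect the organism's enzyme complement, optionally supplemented with
spontaneous (non-enzymatic) reactions.  Reaction directionality is parsed
but analysis is on the simple undirected graph.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx

from coremetnet.data_model import (
    DEFAULT_CURRENCY,
    MetabolicGraph,
    Reaction,
)

logger = logging.getLogger(__name__)

ALL_ENZYMES = "ALL"


def reaction_to_edges(
    reaction: Reaction,
    currency_set: Iterable[str] = DEFAULT_CURRENCY,
) -> set[frozenset[str]]:
    """Undirected carbon-transfer edges contributed by one reaction.

    Returns the reaction's main pairs as unordered pairs, minus any pair
    touching a currency compound and minus self-pairs.  Non-main
    educt-product combinations never become edges.
    """
    currency = frozenset(currency_set)
    edges: set[frozenset[str]] = set()
    for educt, product in reaction.main_pairs:
        if educt == product:
            continue
        if educt in currency or product in currency:
            continue
        edges.add(frozenset((educt, product)))
    return edges


def build_graph(
    reactions: Iterable[Reaction],
    enzymes: Iterable[str] | str = ALL_ENZYMES,
    currency_set: Iterable[str] = DEFAULT_CURRENCY,
    include_spontaneous: bool = True,
    label: str = "",
) -> MetabolicGraph:
    """Build a metabolite graph from the reactions selected by an enzyme list.

    A reaction contributes its edges when its EC set intersects ``enzymes``
    (pass ``"ALL"`` for the reference graph spanning every reaction), or when
    it is spontaneous and ``include_spontaneous`` is set.  Parallel
    contributions collapse to a single edge annotated with all supporting
    reaction ids; nodes are exactly the edge endpoints (no degree-0 nodes).
    """
    select_all = isinstance(enzymes, str)
    if select_all and enzymes != ALL_ENZYMES:
        raise ValueError(f"enzymes must be a set of ECs or {ALL_ENZYMES!r}")
    enzyme_set = frozenset() if select_all else frozenset(enzymes)

    g = nx.Graph()
    for reaction in reactions:
        selected = (
            select_all
            or bool(reaction.ec_numbers & enzyme_set)
            or (include_spontaneous and reaction.spontaneous)
        )
        if select_all and reaction.spontaneous and not include_spontaneous:
            selected = False
        if not selected:
            continue
        for edge in reaction_to_edges(reaction, currency_set):
            u, v = tuple(edge)
            if g.has_edge(u, v):
                g.edges[u, v]["reactions"].add(reaction.reaction_id)
            else:
                g.add_edge(u, v, reactions={reaction.reaction_id})
    if g.number_of_nodes() == 0:
        logger.warning("build_graph(%s): resulting graph is empty", label or "?")
    return MetabolicGraph(g, label=label)


def trim_isolated_edges(graph: MetabolicGraph) -> tuple[MetabolicGraph, int]:
    """Remove every 2-node connected component (isolated edge).

    Returns the trimmed graph and the number of components removed.
    Idempotent; the input graph is not modified.
    """
    g = graph.graph.copy()
    n_removed = 0
    for component in list(nx.connected_components(g)):
        if len(component) == 2:
            g.remove_nodes_from(component)
            n_removed += 1
    return MetabolicGraph(g, label=graph.label), n_removed


__all__ = ["ALL_ENZYMES", "reaction_to_edges", "build_graph", "trim_isolated_edges"]
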