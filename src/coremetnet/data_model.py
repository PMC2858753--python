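"""Domain types and tabular/graph I/O.

The canonical exchange format is UTF-8 tab-delimited text with multi-valued
cells joined by ``";"``.  Reaction tables carry one biochemical reaction per
row; organism profiles carry one organism per row with its EC-number
complement.  Graphs are simple undirected metabolite graphs (each compound
appears once; reaction multiplicity lives in edge annotations), exportable
as GraphML, SIF or plain edge lists.

Compound and reaction identifiers are opaque strings.  KEGG-style ``C#####``
/ ``R#####`` keys are welcome but never validated, so synthetic universes
are first-class citizens.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Ubiquitous cofactors/carriers excluded as graph nodes so that they do not
#: become artifactual hubs.  Configuration, not chemistry: pass your own set
#: (e.g. KEGG C-numbers) when your universe uses different identifiers.
DEFAULT_CURRENCY: frozenset[str] = frozenset(
    {
        "ATP", "ADP", "AMP",
        "NAD+", "NADH", "NADP+", "NADPH",
        "CoA", "H2O", "CO2", "Pi", "PPi", "H+", "O2", "NH3",
    }
)

#: Default identifiers used for cofactor classification of reactions.
DEFAULT_ATP_IDS: frozenset[str] = frozenset({"ATP"})
DEFAULT_NAD_IDS: frozenset[str] = frozenset({"NADH", "NADPH"})

VALID_CATEGORIES = ("F", "FP", "OP")


class SchemaError(ValueError):
    """A required column is missing or a file is structurally unusable."""


class ValidationError(ValueError):
    """A row violates a domain invariant (carries the offending record id)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compound:
    """A metabolite; ``is_currency`` marks members of the currency set."""

    compound_id: str
    name: str = ""
    is_currency: bool = False

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """One biochemical transformation.

    ``main_pairs`` are the curated carbon-transfer (educt, product) pairs —
    the only participants that become graph edges.  ``uses_atp`` /
    ``uses_nad`` classify the full reaction equation (before currency
    filtering): ATP consumption is educt-side, NAD(P)H usage either side.
    """

    reaction_id: str
    ec_numbers: frozenset[str] = frozenset()
    educts: frozenset[str] = frozenset()
    products: frozenset[str] = frozenset()
    main_pairs: frozenset[tuple[str, str]] = frozenset()
    spontaneous: bool = False
    pathway_ids: frozenset[str] = frozenset()
    uses_atp: bool = False
    uses_nad: bool = False

    def __post_init__(self) -> None:
        participants = self.educts | self.products
        for educt, product in self.main_pairs:
            if educt not in participants or product not in participants:
                raise ValidationError(
                    f"reaction {self.reaction_id!r}: main pair "
                    f"({educt!r}, {product!r}) has a member outside "
                    "educts ∪ products"
                )
        if self.spontaneous and self.ec_numbers:
            raise ValidationError(
                f"reaction {self.reaction_id!r}: spontaneous reactions carry "
                "no EC numbers"
            )


@dataclass(frozen=True)
class OrganismProfile:
    """Organism metadata plus its enzyme (EC-number) complement.

    ``category`` is ``"F"`` (free-living), ``"FP"`` (facultative parasite)
    or ``"OP"`` (obligate endoparasite).
    """

    code: str
    name: str = ""
    classification: str = ""
    category: str = "F"
    enzymes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.category not in VALID_CATEGORIES:
            raise ValidationError(
                f"organism {self.code!r}: category {self.category!r} not in "
                f"{VALID_CATEGORIES}"
            )


class MetabolicGraph:
    """Simple undirected metabolite graph with reaction-annotated edges.

    Thin wrapper around :class:`networkx.Graph`.  Invariants: no self-loops,
    no parallel edges (multiplicity is recorded in the per-edge ``reactions``
    annotation), and no degree-0 nodes after construction.
    """

    def __init__(self, graph: nx.Graph | None = None, label: str = "") -> None:
        self.graph = graph if graph is not None else nx.Graph()
        self.label = label

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        annotations: Mapping[frozenset[str], Iterable[str]] | None = None,
        label: str = "",
    ) -> "MetabolicGraph":
        g = nx.Graph()
        for u, v in edges:
            if u == v:
                raise ValidationError(f"self-loop on {u!r} is not allowed")
            key = frozenset((u, v))
            rxns = set(annotations.get(key, ())) if annotations else set()
            if g.has_edge(u, v):
                g.edges[u, v]["reactions"] |= rxns
            else:
                g.add_edge(u, v, reactions=rxns)
        return cls(g, label=label)

    # -- set-style views ----------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def edge_annotations(self) -> dict[frozenset[str], set[str]]:
        return {
            frozenset((u, v)): set(data.get("reactions", ()))
            for u, v, data in self.graph.edges(data=True)
        }

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def copy(self) -> "MetabolicGraph":
        return MetabolicGraph(self.graph.copy(), label=self.label)

    def is_subgraph_of(self, other: "MetabolicGraph") -> bool:
        return self.nodes <= other.nodes and self.edges <= other.edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return (
            f"MetabolicGraph(label={self.label!r}, "
            f"n_nodes={self.n_nodes}, n_edges={self.n_edges})"
        )


@dataclass(frozen=True)
class GraphMetrics:
    """The standard panel of whole-graph statistics.

    ``density`` is ``None`` (missing) for graphs with fewer than two nodes.
    ``avg_path_length`` averages finite shortest-path lengths over *all*
    unordered node pairs (disconnected pairs contribute 0 to the numerator
    but stay in the denominator); ``diameter`` is the longest finite
    shortest path.  ``global_clustering`` is transitivity.
    ``isolated_edges`` counts connected components of exactly two nodes.
    """

    n_nodes: int
    n_edges: int
    density: float | None
    avg_connectivity: float
    max_connectivity: int
    avg_path_length: float
    diameter: int
    global_clustering: float
    isolated_edges: int

    def as_dict(self) -> dict[str, float | int | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class DegreeDistribution:
    """Map degree k (>= 1) -> number of nodes of that degree."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.counts):
            raise ValidationError("degree distribution keys must be >= 1")

    @property
    def n_nodes(self) -> int:
        return sum(self.counts.values())

    def items(self):
        return sorted(self.counts.items())


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------

def _split_multi(cell: object) -> list[str]:
    """Split a ';'-joined cell, tolerating NaN/empty cells."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [part.strip() for part in text.split(";") if part.strip()]


def _parse_bool(cell: object) -> bool:
    if isinstance(cell, bool):
        return cell
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return False
    return str(cell).strip().lower() in {"1", "true", "yes", "y"}


def _parse_pair(token: str, reaction_id: str) -> tuple[str, str]:
    if ">" not in token:
        raise ValidationError(
            f"reaction {reaction_id!r}: main pair {token!r} is not of the "
            "form 'educt>product'"
        )
    educt, product = token.split(">", 1)
    return educt.strip(), product.strip()


REACTION_REQUIRED_COLUMNS = (
    "reaction_id",
    "ec_numbers",
    "educts",
    "products",
    "main_pairs",
)


def read_reaction_table(
    path: str | Path,
    currency_set: Iterable[str] = DEFAULT_CURRENCY,
    atp_ids: Iterable[str] = DEFAULT_ATP_IDS,
    nad_ids: Iterable[str] = DEFAULT_NAD_IDS,
) -> tuple[list[Reaction], dict[str, Compound]]:
    """Read a reaction table (tab-delimited, ';'-joined multi-values).

    Required columns: ``reaction_id``, ``ec_numbers``, ``educts``,
    ``products``, ``main_pairs``.  Optional: ``spontaneous``,
    ``pathway_ids``.  Main pairs are written ``educt>product``.

    Returns the reactions in file order plus a registry of every
    participating compound, flagged with membership of ``currency_set``.
    Cofactor flags are derived from the full equation: ``uses_atp`` iff an
    ATP identifier appears among the educts, ``uses_nad`` iff an NAD(P)H
    identifier appears on either side.
    """
    currency = frozenset(currency_set)
    atp = frozenset(atp_ids)
    nad = frozenset(nad_ids)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REACTION_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )

    reactions: list[Reaction] = []
    compounds: dict[str, Compound] = {}
    for row in df.itertuples(index=False):
        rid = str(row.reaction_id).strip()
        educts = frozenset(_split_multi(row.educts))
        products = frozenset(_split_multi(row.products))
        pairs = frozenset(
            _parse_pair(tok, rid) for tok in _split_multi(row.main_pairs)
        )
        spontaneous = _parse_bool(getattr(row, "spontaneous", False))
        reaction = Reaction(
            reaction_id=rid,
            ec_numbers=frozenset(_split_multi(row.ec_numbers)),
            educts=educts,
            products=products,
            main_pairs=pairs,
            spontaneous=spontaneous,
            pathway_ids=frozenset(_split_multi(getattr(row, "pathway_ids", ""))),
            uses_atp=bool(educts & atp),
            uses_nad=bool((educts | products) & nad),
        )
        reactions.append(reaction)
        for cid in educts | products:
            if cid not in compounds:
                compounds[cid] = Compound(
                    compound_id=cid, name=cid, is_currency=cid in currency
                )
    return reactions, compounds


PROFILE_REQUIRED_COLUMNS = ("code", "name", "classification", "category", "enzymes")


def read_organism_profiles(path: str | Path) -> list[OrganismProfile]:
    """Read organism profiles (tab-delimited; enzymes ';'-joined).

    Profiles are returned in file order; duplicate EC numbers within a row
    collapse.  An empty file yields an empty list with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PROFILE_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    if df.empty:
        logger.warning("%s: organism profile table is empty", path)
        return []
    return [
        OrganismProfile(
            code=str(row.code).strip(),
            name=str(row.name).strip(),
            classification=str(row.classification).strip(),
            category=str(row.category).strip(),
            enzymes=frozenset(_split_multi(row.enzymes)),
        )
        for row in df.itertuples(index=False)
    ]


def write_reaction_table(
    reactions: Sequence[Reaction], path: str | Path
) -> None:
    """Write reactions in the canonical tab-delimited schema."""
    records = [
        {
            "reaction_id": r.reaction_id,
            "ec_numbers": ";".join(sorted(r.ec_numbers)),
            "educts": ";".join(sorted(r.educts)),
            "products": ";".join(sorted(r.products)),
            "main_pairs": ";".join(
                f"{e}>{p}" for e, p in sorted(r.main_pairs)
            ),
            "spontaneous": int(r.spontaneous),
            "pathway_ids": ";".join(sorted(r.pathway_ids)),
        }
        for r in reactions
    ]
    pd.DataFrame.from_records(
        records,
        columns=[*REACTION_REQUIRED_COLUMNS, "spontaneous", "pathway_ids"],
    ).to_csv(path, sep="\t", index=False)


def write_organism_profiles(
    profiles: Sequence[OrganismProfile], path: str | Path
) -> None:
    records = [
        {
            "code": p.code,
            "name": p.name,
            "classification": p.classification,
            "category": p.category,
            "enzymes": ";".join(sorted(p.enzymes)),
        }
        for p in profiles
    ]
    pd.DataFrame.from_records(records, columns=list(PROFILE_REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# graph writers/readers
# ---------------------------------------------------------------------------

GRAPH_FORMATS = ("graphml", "sif", "edgelist")


def write_graph(
    graph: MetabolicGraph, path: str | Path, format: str = "graphml"
) -> None:
    """Export a graph as GraphML, SIF or a plain edge list.

    Edge annotations (supporting reaction ids) are serialized in GraphML and
    used as the SIF interaction label; the edge-list format keeps endpoints
    only.  Reading the file back yields identical node and edge sets.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(graph.graph.nodes)
        for u, v, data in graph.graph.edges(data=True):
            g.add_edge(u, v, reactions=";".join(sorted(data.get("reactions", ()))))
        nx.write_graphml(g, path)
    elif format == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for u, v, data in sorted(
                graph.graph.edges(data=True), key=lambda e: sorted(e[:2])
            ):
                rxns = ";".join(sorted(data.get("reactions", ()))) or "rxn"
                a, b = sorted((u, v))
                fh.write(f"{a}\t{rxns}\t{b}\n")
    elif format == "edgelist":
        with path.open("w", encoding="utf-8") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in graph.graph.edges):
                fh.write(f"{u}\t{v}\n")
    else:
        raise ValueError(
            f"unknown graph format {format!r}; expected one of {GRAPH_FORMATS}"
        )


def read_graph(path: str | Path, format: str = "graphml", label: str = "") -> MetabolicGraph:
    """Read a graph written by :func:`write_graph`."""
    path = Path(path)
    g = nx.Graph()
    if format == "graphml":
        raw = nx.read_graphml(path)
        for node in raw.nodes:
            g.add_node(str(node))
        for u, v, data in raw.edges(data=True):
            rxns = set(filter(None, str(data.get("reactions", "")).split(";")))
            g.add_edge(str(u), str(v), reactions=rxns)
    elif format == "sif":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                u, rxns, v = parts[0], parts[1], parts[2]
                ann = set(filter(None, rxns.split(";"))) - {"rxn"}
                g.add_edge(u, v, reactions=ann)
    elif format == "edgelist":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 2:
                    g.add_edge(parts[0], parts[1], reactions=set())
    else:
        raise ValueError(
            f"unknown graph format {format!r}; expected one of {GRAPH_FORMATS}"
        )
    return MetabolicGraph(g, label=label)


# ---------------------------------------------------------------------------
# metrics report writer
# ---------------------------------------------------------------------------

def _group_summary(
    rows: Sequence[tuple[str, GraphMetrics]],
    categories: Mapping[str, str],
) -> dict[str, dict[str, dict[str, float]]]:
    """Per-category mean and SD (ddof=1; SD is NaN for singleton groups)."""
    frame = pd.DataFrame(
        [dict(label=label, category=categories.get(label), **m.as_dict())
         for label, m in rows]
    ).dropna(subset=["category"])
    summaries: dict[str, dict[str, dict[str, float]]] = {}
    metric_cols = GraphMetrics.field_names()
    for cat, sub in frame.groupby("category"):
        values = sub[metric_cols].astype(float)
        summaries[str(cat)] = {
            "n": {"value": float(len(sub))},
            "mean": values.mean().to_dict(),
            "sd": values.std(ddof=1).to_dict(),
        }
    return summaries


def write_metrics_report(
    rows: Sequence[tuple[str, GraphMetrics]],
    path: str | Path,
    format: str = "tsv",
    categories: Mapping[str, str] | None = None,
) -> None:
    """Write per-graph metrics, one record per graph.

    When ``categories`` maps labels to group tags, per-group mean ± SD
    summaries are appended (TSV) or nested under ``"groups"`` (JSON).
    """
    if not rows:
        raise ValueError("write_metrics_report requires at least one row")
    path = Path(path)
    metric_cols = GraphMetrics.field_names()
    if format == "tsv":
        frame = pd.DataFrame(
            [dict(label=label, **m.as_dict()) for label, m in rows]
        )
        if categories:
            frame.insert(1, "category", [categories.get(l, "") for l, _ in rows])
            summary = _group_summary(rows, categories)
            extra = []
            for cat, stats_ in sorted(summary.items()):
                for kind in ("mean", "sd"):
                    extra.append(
                        {"label": f"{kind}[{cat}]", "category": cat,
                         **stats_[kind]}
                    )
            frame = pd.concat([frame, pd.DataFrame(extra)], ignore_index=True)
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload: dict = {
            "rows": [
                {"label": label, **m.as_dict()} for label, m in rows
            ],
            "fields": metric_cols,
        }
        if categories:
            payload["groups"] = _group_summary(rows, categories)
        with path.open("w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, allow_nan=True)
    else:
        raise ValueError(f"unknown report format {format!r}; expected tsv or json")


def read_metrics_report(path: str | Path) -> list[tuple[str, GraphMetrics]]:
    """Read back a JSON metrics report (inverse of the JSON writer)."""
    with Path(path).open(encoding="utf-8") as fh:
        payload = json.load(fh)
    out = []
    for row in payload["rows"]:
        row = dict(row)
        label = row.pop("label")
        out.append((label, GraphMetrics(**row)))
    return out


__all__ = [
    "Compound", "Reaction", "OrganismProfile", "MetabolicGraph",
    "GraphMetrics", "DegreeDistribution",
    "DEFAULT_CURRENCY", "DEFAULT_ATP_IDS", "DEFAULT_NAD_IDS",
    "SchemaError", "ValidationError",
    "read_reaction_table", "write_reaction_table",
    "read_organism_profiles", "write_organism_profiles",
    "read_graph", "write_graph",
    "write_metrics_report", "read_metrics_report",
]
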