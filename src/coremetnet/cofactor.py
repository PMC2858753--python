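"""Cofactor-usage analysis: ATP / NAD(P)H retention during network shrinkage.

A reaction is *ATP-consuming* when ATP appears on its educt side (ATP
consumption is directional), and *NAD(P)H-utilizing* when NADH or NADPH
appears on either side (redox cofactors cycle).  Both side rules are
configurable.  Classification looks at the full reaction equation, before
currency filtering: the cofactors are excluded as graph nodes but still
counted here.  Per-organism percentages are taken over the organism's core
reaction count and correlated (Spearman) with that count to quantify the
preferential retention of ATP-requiring reactions in shrinking networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from coremetnet.data_model import (
    DEFAULT_ATP_IDS,
    DEFAULT_NAD_IDS,
    OrganismProfile,
    Reaction,
)
from coremetnet.stats import TestResult, fisher_exact_2x2, spearman_corr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CofactorSummary:
    """Cofactor usage of one organism's core reaction set (percentages)."""

    organism_code: str
    n_reactions: int
    pct_atp: float
    pct_nad: float

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise ValueError(f"{self.organism_code}: n_reactions must be >= 1")
        for pct in (self.pct_atp, self.pct_nad):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{self.organism_code}: percentage {pct} outside [0, 100]")


def classify_reaction_cofactors(
    reaction: Reaction,
    atp_ids: Iterable[str] = DEFAULT_ATP_IDS,
    nad_ids: Iterable[str] = DEFAULT_NAD_IDS,
    atp_side: str = "educts",
    nad_side: str = "both",
) -> tuple[bool, bool]:
    """(uses_atp, uses_nad) for one reaction under configurable side rules.

    ``*_side`` is ``"educts"``, ``"products"`` or ``"both"``.
    """
    atp = frozenset(atp_ids)
    nad = frozenset(nad_ids)
    if not atp or not nad:
        raise ValueError("cofactor id sets must be non-empty")

    def pick(side: str) -> frozenset[str]:
        if side == "educts":
            return reaction.educts
        if side == "products":
            return reaction.products
        if side == "both":
            return reaction.educts | reaction.products
        raise ValueError(f"unknown side rule {side!r}")

    return bool(pick(atp_side) & atp), bool(pick(nad_side) & nad)


def cofactor_summaries(
    reactions: Sequence[Reaction],
    profiles: Sequence[OrganismProfile],
    include_spontaneous: bool = True,
    atp_ids: Iterable[str] = DEFAULT_ATP_IDS,
    nad_ids: Iterable[str] = DEFAULT_NAD_IDS,
    atp_side: str = "educts",
    nad_side: str = "both",
) -> list[CofactorSummary]:
    """Per-organism cofactor-usage percentages over its core reaction set.

    An organism's set is every reaction whose EC numbers intersect its
    enzyme complement (plus spontaneous reactions if configured).
    Organisms selecting no reaction are excluded with a warning.
    """
    summaries: list[CofactorSummary] = []
    for profile in profiles:
        selected = [
            r
            for r in reactions
            if (r.ec_numbers & profile.enzymes)
            or (include_spontaneous and r.spontaneous)
        ]
        if not selected:
            logger.warning(
                "cofactor_summaries: organism %s selects no reactions, excluded",
                profile.code,
            )
            continue
        flags = [
            classify_reaction_cofactors(r, atp_ids, nad_ids, atp_side, nad_side)
            for r in selected
        ]
        n = len(selected)
        summaries.append(
            CofactorSummary(
                organism_code=profile.code,
                n_reactions=n,
                pct_atp=100.0 * sum(a for a, _ in flags) / n,
                pct_nad=100.0 * sum(b for _, b in flags) / n,
            )
        )
    return summaries


def size_cofactor_correlation(
    summaries: Sequence[CofactorSummary], which: str = "atp"
) -> TestResult:
    """Spearman correlation of cofactor percentage vs core reaction count.

    A negative rho for ATP means the smaller an organism's core network,
    the larger its share of ATP-consuming reactions — i.e. ATP-requiring
    reactions resist loss.
    """
    if which not in ("atp", "nad"):
        raise ValueError(f"which must be 'atp' or 'nad', got {which!r}")
    if len(summaries) < 4:
        raise ValueError("size_cofactor_correlation requires >= 4 summaries")
    sizes = [float(s.n_reactions) for s in summaries]
    pcts = [s.pct_atp if which == "atp" else s.pct_nad for s in summaries]
    return spearman_corr(sizes, pcts)


def essentiality_fisher(
    gene_table: Sequence[tuple[str, str, bool]],
) -> tuple[dict[str, tuple[int, float]], TestResult]:
    """Essential-gene fractions per cofactor class plus ATP-vs-NAD Fisher test.

    ``gene_table`` rows are (gene, ec_class, essential) with ec_class in
    {"ATP", "NAD", "other"}.  Returns ``{class: (n_genes, essential
    fraction)}`` and the two-tailed Fisher exact result on the 2x2
    essential-by-class table for the ATP and NAD classes.
    """
    classes: dict[str, list[bool]] = {}
    for _, ec_class, essential in gene_table:
        classes.setdefault(ec_class, []).append(bool(essential))
    for required in ("ATP", "NAD"):
        if not classes.get(required):
            raise ValueError(f"gene table has no genes in class {required!r}")
    fractions = {
        cls: (len(flags), sum(flags) / len(flags)) for cls, flags in classes.items()
    }
    atp_flags = classes["ATP"]
    nad_flags = classes["NAD"]
    table = [
        [sum(atp_flags), len(atp_flags) - sum(atp_flags)],
        [sum(nad_flags), len(nad_flags) - sum(nad_flags)],
    ]
    return fractions, fisher_exact_2x2(table)


__all__ = [
    "CofactorSummary",
    "classify_reaction_cofactors",
    "cofactor_summaries",
    "size_cofactor_correlation",
    "essentiality_fisher",
]
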