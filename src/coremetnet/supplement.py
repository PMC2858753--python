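"""Convert per-organism workbook sheets into the canonical tabular schema.

The published reconstructed networks are distributed as a spreadsheet
workbook with one sheet per organism listing predicted enzymes (EC
number), the corresponding educts and products, the reaction identifier
and the pathway maps.  This module flattens such a workbook into the
package's two canonical TSVs (one reaction universe + one organism
profile table) so the reproduction checks can run on it.

The exact column layout of the workbook is not standardized, so matching
is deliberately tolerant:

* header names are matched case-insensitively by keyword (``ec``/
  ``enzyme``, ``educt``/``substrate``, ``product``, ``reaction``,
  ``pathway``/``map``);
* multi-valued cells may be separated by ``;`` or ``,``;
* a row with equally many educts and products is read as positional
  carbon-transfer pairs; otherwise every educt-product combination not
  involving a currency compound becomes a pair.

Requires ``openpyxl`` (installed with the ``convert`` extra).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from coremetnet.data_model import (
    DEFAULT_ATP_IDS,
    DEFAULT_CURRENCY,
    DEFAULT_NAD_IDS,
    Reaction,
    OrganismProfile,
    write_organism_profiles,
    write_reaction_table,
)

logger = logging.getLogger(__name__)

#: Category and lineage of the 16-organism panel, keyed by the usual
#: three-letter codes; sheets with unknown codes default to free-living.
KNOWN_ORGANISMS = {
    "Hsa": ("Homo sapiens", "Metazoa", "F"),
    "Eco": ("Escherichia coli", "Bacteria", "FP"),
    "Cal": ("Candida albicans", "Fungi", "FP"),
    "Sce": ("Saccharomyces cerevisiae", "Fungi", "F"),
    "Spo": ("Schizosaccharomyces pombe", "Fungi", "F"),
    "Ddi": ("Dictyostelium discoideum", "Amoebozoa", "F"),
    "Dme": ("Drosophila melanogaster", "Metazoa", "F"),
    "Cel": ("Caenorhabditis elegans", "Metazoa", "F"),
    "Tcr": ("Trypanosoma cruzi", "Euglenozoa", "OP"),
    "Lma": ("Leishmania major", "Euglenozoa", "OP"),
    "Tbr": ("Trypanosoma brucei", "Euglenozoa", "OP"),
    "Pfa": ("Plasmodium falciparum", "Apicomplexa", "OP"),
    "Ehi": ("Entamoeba histolytica", "Amoebozoa", "OP"),
    "Tpa": ("Theileria parva", "Apicomplexa", "OP"),
    "Cho": ("Cryptosporidium hominis", "Apicomplexa", "OP"),
    "Ecu": ("Encephalitozoon cuniculi", "Fungi", "OP"),
}

_COLUMN_KEYWORDS = {
    "ec_numbers": ("ec", "enzyme"),
    "educts": ("educt", "substrate"),
    "products": ("product",),
    "reaction_id": ("reaction",),
    "pathway_ids": ("pathway", "map"),
}


def _match_columns(header: list[str]) -> dict[str, int]:
    mapping: dict[str, int] = {}
    for idx, cell in enumerate(header):
        name = str(cell or "").strip().lower()
        if not name:
            continue
        for field, keywords in _COLUMN_KEYWORDS.items():
            if field not in mapping and any(kw in name for kw in keywords):
                mapping[field] = idx
                break
    missing = {"ec_numbers", "educts", "products", "reaction_id"} - set(mapping)
    if missing:
        raise ValueError(f"could not locate column(s): {sorted(missing)}")
    return mapping


def _split(cell: object) -> list[str]:
    text = str(cell if cell is not None else "").strip()
    if not text or text.lower() in ("nan", "none"):
        return []
    return [p.strip() for p in re.split(r"[;,]", text) if p.strip()]


def _pairs(educts: list[str], products: list[str], currency: frozenset[str]):
    if educts and len(educts) == len(products):
        combos = list(zip(educts, products))
    else:
        combos = [(e, p) for e in educts for p in products]
    return {
        (e, p)
        for e, p in combos
        if e != p and e not in currency and p not in currency
    }


def convert_workbook(
    workbook_path: str | Path,
    out_dir: str | Path,
    currency_set: frozenset[str] = DEFAULT_CURRENCY,
    atp_ids: frozenset[str] = DEFAULT_ATP_IDS,
    nad_ids: frozenset[str] = DEFAULT_NAD_IDS,
) -> tuple[Path, Path]:
    """Flatten a one-sheet-per-organism workbook into canonical TSVs.

    Returns the paths of the written ``reactions.tsv`` and
    ``organisms.tsv``.  Reactions seen in several sheets are merged (the
    union of their annotations); each organism profile carries the EC
    numbers of its own sheet.
    """
    import openpyxl

    wb = openpyxl.load_workbook(workbook_path, read_only=True, data_only=True)
    reactions: dict[str, dict] = {}
    profiles: list[OrganismProfile] = []

    for sheet in wb.worksheets:
        rows = sheet.iter_rows(values_only=True)
        try:
            header = next(rows)
        except StopIteration:
            logger.warning("sheet %s is empty, skipped", sheet.title)
            continue
        columns = _match_columns(list(header))
        enzymes: set[str] = set()
        for row in rows:
            def cell(field, default=""):
                idx = columns.get(field)
                return row[idx] if idx is not None and idx < len(row) else default

            rid = str(cell("reaction_id") or "").strip()
            if not rid:
                continue
            ecs = set(_split(cell("ec_numbers")))
            educts = _split(cell("educts"))
            products = _split(cell("products"))
            pathways = set(_split(cell("pathway_ids")))
            enzymes |= ecs
            entry = reactions.setdefault(
                rid,
                {"ec": set(), "educts": set(), "products": set(),
                 "pairs": set(), "pathways": set()},
            )
            entry["ec"] |= ecs
            entry["educts"] |= set(educts)
            entry["products"] |= set(products)
            entry["pairs"] |= _pairs(educts, products, currency_set)
            entry["pathways"] |= pathways
        code = sheet.title.strip()
        name, classification, category = KNOWN_ORGANISMS.get(
            code, (code, "", "F")
        )
        if code not in KNOWN_ORGANISMS:
            logger.warning(
                "sheet %s is not a recognized organism code; category "
                "defaults to F", code
            )
        profiles.append(
            OrganismProfile(
                code=code, name=name, classification=classification,
                category=category, enzymes=frozenset(enzymes),
            )
        )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reaction_objs = [
        Reaction(
            reaction_id=rid,
            ec_numbers=frozenset(entry["ec"]),
            educts=frozenset(entry["educts"]),
            products=frozenset(entry["products"]),
            main_pairs=frozenset(entry["pairs"]),
            spontaneous=not entry["ec"],
            pathway_ids=frozenset(entry["pathways"]),
            uses_atp=bool(entry["educts"] & atp_ids),
            uses_nad=bool((entry["educts"] | entry["products"]) & nad_ids),
        )
        for rid, entry in sorted(reactions.items())
    ]
    reactions_path = out / "reactions.tsv"
    profiles_path = out / "organisms.tsv"
    write_reaction_table(reaction_objs, reactions_path)
    write_organism_profiles(profiles, profiles_path)
    logger.info(
        "converted %d reactions, %d organisms", len(reaction_objs), len(profiles)
    )
    return reactions_path, profiles_path


__all__ = ["KNOWN_ORGANISMS", "convert_workbook"]
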