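"""End-to-end study orchestration.

``run_pipeline`` is a pure function of (inputs, config, seed): it loads (or
simulates) a reaction universe and organism cohort, builds the reference
and per-organism graphs, computes the metrics panel, compares parasite and
non-parasite groups, runs the random-shrinkage null ensemble, the
cofactor-retention analysis and the degree-distribution/power-law fits,
and writes every table to the output directory together with a run log.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import coremetnet
from coremetnet.cofactor import cofactor_summaries, size_cofactor_correlation
from coremetnet.data_model import (
    DEFAULT_ATP_IDS,
    DEFAULT_CURRENCY,
    DEFAULT_NAD_IDS,
    GraphMetrics,
    MetabolicGraph,
    read_organism_profiles,
    read_reaction_table,
    write_graph,
    write_metrics_report,
    write_organism_profiles,
    write_reaction_table,
)
from coremetnet.graph_build import ALL_ENZYMES, build_graph, trim_isolated_edges
from coremetnet.graph_metrics import (
    compute_metrics,
    degree_distribution,
    fit_power_law_tail,
)
from coremetnet.shrinkage import shrink_ensemble
from coremetnet.stats import kruskal_wallis_dunn, mann_whitney
from coremetnet.synthetic_data import SyntheticStudyTruth, generate_study

logger = logging.getLogger(__name__)

PARASITE_CATEGORY = "OP"


@dataclass
class StudyConfig:
    """Configuration for one pipeline run.

    When ``reactions_path``/``profiles_path`` are unset, a synthetic study
    is generated from ``seed`` and written under the output directory, so
    the pipeline runs end-to-end with no external data.
    """

    out_dir: Path
    seed: int
    reactions_path: Path | None = None
    profiles_path: Path | None = None
    currency_set: frozenset[str] = DEFAULT_CURRENCY
    atp_ids: frozenset[str] = DEFAULT_ATP_IDS
    nad_ids: frozenset[str] = DEFAULT_NAD_IDS
    include_spontaneous: bool = True
    trim: bool = False
    clustering: str = "transitivity"
    atp_side: str = "educts"
    nad_side: str = "both"
    shrink_target: int | None = None
    shrink_replicates: int = 10
    n_reactions: int = 1200
    write_graphs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("out_dir", "reactions_path", "profiles_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        for key in ("currency_set", "atp_ids", "nad_ids"):
            if raw.get(key) is not None:
                raw[key] = frozenset(raw[key])
        return cls(**raw)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _group_test_rows(
    metrics_by_label: dict[str, GraphMetrics],
    categories: Mapping[str, str],
) -> dict[str, dict[str, float]]:
    """Parasite vs non-parasite Mann-Whitney per metric field."""
    parasites = [m for l, m in metrics_by_label.items() if categories[l] == PARASITE_CATEGORY]
    others = [m for l, m in metrics_by_label.items() if categories[l] != PARASITE_CATEGORY]
    out: dict[str, dict[str, float]] = {}
    for name in GraphMetrics.field_names():
        a = [getattr(m, name) for m in parasites]
        b = [getattr(m, name) for m in others]
        if any(v is None for v in a + b):
            continue
        mode = "exact" if len(a) + len(b) <= 20 else "approximate"
        res = mann_whitney([float(v) for v in a], [float(v) for v in b], mode=mode)
        out[name] = {
            "U": res.statistic,
            "p": res.p_value,
            "mean_parasite": float(np.mean(a)),
            "mean_nonparasite": float(np.mean(b)),
        }
    return out


def run_pipeline(config: StudyConfig) -> dict[str, Any]:
    """Run the full comparative study; returns the report dictionary.

    Writes (under ``config.out_dir``): the simulated inputs (if any),
    ``metrics.tsv``/``metrics.json``, per-organism GraphML, ``ensemble.json``,
    ``cofactors.tsv``, ``degree_dist.tsv``, ``report.json`` and
    ``run_log.json``.  Deterministic given config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs ----------------------------------------------------------
    if config.reactions_path is None or config.profiles_path is None:
        truth = SyntheticStudyTruth(seed=config.seed, n_reactions=config.n_reactions,
                                    currency_set=config.currency_set)
        bundle = generate_study(truth)
        reactions, profiles = list(bundle.reactions), list(bundle.profiles)
        inputs_dir = out / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        write_reaction_table(reactions, inputs_dir / "reactions.tsv")
        write_organism_profiles(profiles, inputs_dir / "organisms.tsv")
        input_origin = "synthetic"
    else:
        reactions, _ = read_reaction_table(
            config.reactions_path, config.currency_set, config.atp_ids, config.nad_ids
        )
        profiles = read_organism_profiles(config.profiles_path)
        input_origin = "files"
    if not profiles:
        raise ValueError("pipeline stage 'inputs': no organism profiles")

    # ---- graphs ----------------------------------------------------------
    reference = build_graph(
        reactions, ALL_ENZYMES, config.currency_set,
        include_spontaneous=config.include_spontaneous, label="reference",
    )
    graphs: dict[str, MetabolicGraph] = {"reference": reference}
    categories: dict[str, str] = {"reference": "reference"}
    for profile in profiles:
        g = build_graph(
            reactions, profile.enzymes, config.currency_set,
            include_spontaneous=config.include_spontaneous, label=profile.code,
        )
        graphs[profile.code] = g
        categories[profile.code] = profile.category
    trim_counts: dict[str, int] = {}
    if config.trim:
        for label, g in graphs.items():
            trimmed, n_removed = trim_isolated_edges(g)
            graphs[label] = trimmed
            trim_counts[label] = n_removed

    # ---- metrics ---------------------------------------------------------
    metrics_by_label = {
        label: compute_metrics(g, clustering=config.clustering)
        for label, g in graphs.items()
    }
    rows = [(label, m) for label, m in metrics_by_label.items()]
    write_metrics_report(rows, out / "metrics.tsv", "tsv", categories)
    write_metrics_report(rows, out / "metrics.json", "json", categories)
    if config.write_graphs:
        graphs_dir = out / "graphs"
        graphs_dir.mkdir(exist_ok=True)
        for label, g in graphs.items():
            write_graph(g, graphs_dir / f"{label}.graphml", "graphml")

    organism_metrics = {
        l: m for l, m in metrics_by_label.items() if l != "reference"
    }
    group_tests = _group_test_rows(organism_metrics, categories)

    # ---- shrinkage null --------------------------------------------------
    parasite_edges = [
        m.n_edges for l, m in organism_metrics.items()
        if categories[l] == PARASITE_CATEGORY
    ]
    target = config.shrink_target
    if target is None:
        target = int(round(np.mean(parasite_edges))) if parasite_edges else reference.n_edges // 4
    target = min(target, reference.n_edges)
    ensemble = shrink_ensemble(
        reference, target, config.shrink_replicates, seed=config.seed
    )

    # omnibus comparison of parasites / non-parasites / random replicates
    kw_results: dict[str, dict[str, Any]] = {}
    for name in ("diameter", "isolated_edges", "global_clustering", "avg_path_length"):
        groups = [
            [float(getattr(m, name)) for l, m in organism_metrics.items()
             if categories[l] == PARASITE_CATEGORY],
            [float(getattr(m, name)) for l, m in organism_metrics.items()
             if categories[l] != PARASITE_CATEGORY],
            [float(getattr(m, name)) for m in ensemble.per_replicate],
        ]
        if min(len(g) for g in groups) == 0:
            continue
        omnibus, pairwise = kruskal_wallis_dunn(groups)
        kw_results[name] = {
            "H": omnibus.statistic,
            "p": omnibus.p_value,
            "dunn": [
                {"pair": r.method, "z": r.statistic, "p_adjusted": r.p_value}
                for r in pairwise
            ],
        }

    # ---- cofactors -------------------------------------------------------
    summaries = cofactor_summaries(
        reactions, profiles,
        include_spontaneous=config.include_spontaneous,
        atp_ids=config.atp_ids, nad_ids=config.nad_ids,
        atp_side=config.atp_side, nad_side=config.nad_side,
    )
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out / "cofactors.tsv", sep="\t", index=False
    )
    cofactor_block: dict[str, Any] = {
        "summaries": [asdict(s) for s in summaries],
    }
    if len(summaries) >= 4:
        for which in ("atp", "nad"):
            res = size_cofactor_correlation(summaries, which)
            cofactor_block[f"rho_{which}"] = res.statistic
            cofactor_block[f"p_{which}"] = res.p_value

    # per-group cofactor Mann-Whitney (percent ATP, parasites vs others)
    pct_atp_par = [s.pct_atp for s in summaries
                   if categories.get(s.organism_code) == PARASITE_CATEGORY]
    pct_atp_non = [s.pct_atp for s in summaries
                   if categories.get(s.organism_code) not in (PARASITE_CATEGORY, None)]
    if pct_atp_par and pct_atp_non:
        mode = "exact" if len(pct_atp_par) + len(pct_atp_non) <= 20 else "approximate"
        res = mann_whitney(pct_atp_par, pct_atp_non, mode=mode)
        cofactor_block["pct_atp_group_test"] = {"U": res.statistic, "p": res.p_value}

    # ---- degree distributions & power-law tails --------------------------
    dist_rows = []
    power_law: dict[str, dict[str, float]] = {}
    for label, g in graphs.items():
        dist = degree_distribution(g)
        for k, c in dist.items():
            dist_rows.append({"label": label, "degree": k, "count": c})
        try:
            fit = fit_power_law_tail(dist, k_min=2)
            power_law[label] = {
                "slope": fit.slope, "intercept": fit.intercept,
                "r_squared": fit.r_squared, "k_min": fit.k_min,
            }
        except ValueError:
            logger.warning("power-law fit skipped for %s (thin tail)", label)
    pooled = ensemble.pooled_degree_distribution
    for k, c in pooled.items():
        dist_rows.append({"label": "random", "degree": k, "count": c})
    try:
        fit = fit_power_law_tail(pooled, k_min=2)
        power_law["random"] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.r_squared, "k_min": fit.k_min,
        }
    except ValueError:
        pass
    pd.DataFrame(dist_rows).to_csv(out / "degree_dist.tsv", sep="\t", index=False)

    # ---- report & run log ------------------------------------------------
    report: dict[str, Any] = {
        "input_origin": input_origin,
        "n_reactions": len(reactions),
        "n_organisms": len(profiles),
        "categories": categories,
        "metrics": {l: m.as_dict() for l, m in metrics_by_label.items()},
        "trim_counts": trim_counts,
        "group_tests": group_tests,
        "shrinkage": {
            "target_edges": ensemble.target_edges,
            "n_replicates": ensemble.n_replicates,
            "summary": ensemble.summary,
        },
        "kruskal_wallis": kw_results,
        "cofactor": cofactor_block,
        "power_law": power_law,
    }
    with (out / "report.json").open("w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=1)
    run_log = {
        "package_version": coremetnet.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {k: _jsonable(v) for k, v in asdict(config).items()},
        "decisions": {
            "clustering": config.clustering,
            "atp_side": config.atp_side,
            "nad_side": config.nad_side,
            "trim": config.trim,
            "path_length_convention": "finite pairs over N(N-1)/2",
            "shrink_unit": "graph edges",
        },
    }
    with (out / "run_log.json").open("w", encoding="utf-8") as fh:
        json.dump(_jsonable(run_log), fh, indent=1)
    return report


__all__ = ["StudyConfig", "run_pipeline", "PARASITE_CATEGORY"]
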