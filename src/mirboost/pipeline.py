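"""End-to-end pipeline: preprocessing, network boosting, pathway analysis.

``run_pipeline`` drives the three stages over a declarative config:

1. preprocessing — normalize miRNA names, map gene symbols to Entrez, read
   and combine the miRNA-target databases, read and confidence-filter the
   PPI network;
2. boosting — seed construction (DEG ∩ DER-target by default, degrading
   gracefully to whichever list is supplied), random walk with restart, and
   boosted-set extraction at each configured level;
3. pathway analysis — hypergeometric enrichment per gene set, the
   permutation null for the enriched-pathway count, cross-level dot-plot
   table, hub/centrality report, and the miRNA-gene overlay export.

Given the same config and seed, all tabular outputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    count_enriched,
    dotplot_table,
    enrich,
    permutation_null,
    read_gmt,
    write_enrichment_table,
)
from .graph_metrics import (
    build_overlay,
    eigenvector_centrality,
    export_graph,
    find_hubs,
    induced_subnetwork,
    write_centrality_table,
)
from .identifiers import IdMapTable, map_symbols, normalize_mirna, read_known_mirnas
from .interactions import combine_databases, load_dialects, read_target_table, targets_of
from .ppi_network import build_transition_matrix, filter_top_fraction, read_edge_list
from .propagation import (
    classify_connectivity,
    construct_seed_set,
    make_restart_vector,
    rwr,
    select_boosted,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    id_map: str = ""
    known_mirnas: str = ""
    ppi: str = ""
    gmt: str = ""
    out_dir: str = "results"
    der_list: str | None = None
    deg_list: str | None = None
    target_dbs: list[dict] = field(default_factory=list)  # {path, dialect}
    db_mode: str = "intersection"
    seed_mode: str = "intersection"
    ppi_dialect: str = "string-links"
    ppi_top_fraction: float = 0.01
    restart_p: float = 0.7
    rwr_tol: float = 1e-10
    rwr_max_iter: int = 1000
    boost_levels: list[float] = field(default_factory=lambda: [0.01, 0.10, 0.20])
    enrichment_threshold: float = 0.01
    use_adjusted_p: bool = False
    min_overlap: int = 1
    n_perm: int = 10000
    hub_k: int = 3
    dialect_config: str | None = None
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def validate_config(config: PipelineConfig) -> list[tuple[str, str]]:
    """Classify config findings as ("error"|"warning", message)."""
    findings: list[tuple[str, str]] = []
    for name in ("id_map", "known_mirnas", "ppi", "gmt"):
        path = getattr(config, name)
        if not path:
            findings.append(("error", f"missing required path: {name}"))
        elif not Path(path).exists():
            findings.append(("error", f"{name} path does not exist: {path}"))
    if config.der_list is None and config.deg_list is None:
        findings.append(("error", "need at least one of der_list / deg_list"))
    for name in ("der_list", "deg_list"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            findings.append(("error", f"{name} path does not exist: {path}"))
    if config.der_list is not None and not config.target_dbs:
        findings.append(("error", "der_list given but no target_dbs configured"))
    for db in config.target_dbs:
        if "path" not in db:
            findings.append(("error", f"target_db entry lacks 'path': {db}"))
        elif not Path(db["path"]).exists():
            findings.append(("error", f"target_db path does not exist: {db['path']}"))
    if not 0 < config.ppi_top_fraction <= 1:
        findings.append(("error", f"ppi_top_fraction out of (0,1]: {config.ppi_top_fraction}"))
    if not 0 < config.restart_p <= 1:
        findings.append(("error", f"restart_p out of (0,1]: {config.restart_p}"))
    for lv in config.boost_levels:
        if not 0 <= lv <= 1:
            findings.append(("error", f"boost level out of [0,1]: {lv}"))
    if config.db_mode not in ("intersection", "union", "single"):
        findings.append(("error", f"unknown db_mode: {config.db_mode}"))
    if config.n_perm < 1:
        findings.append(("error", f"n_perm must be >= 1: {config.n_perm}"))
    if config.restart_p == 0.7:
        findings.append(("warning", "restart_p using default 0.7"))
    return findings


def _level_tag(level: float) -> str:
    return f"{level * 100:g}pct"


def _read_list(path: str | Path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            token = line.strip().split("\t")[0]
            if token:
                out.append(token)
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline; returns the results directory.

    Writes seeds.tsv, scores.tsv, boosted_<level>.tsv, enrichment_seed.tsv,
    enrichment_<level>.tsv, permutation_<level>.tsv, dotplot.tsv,
    network.graphml, network.json, hubs.tsv, centrality.tsv, manifest.json
    and run.log.
    """
    findings = validate_config(config)
    errors = [msg for lvl, msg in findings if lvl == "error"]
    if errors:
        raise ValueError("; ".join(errors))

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mirboost")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t_start = time.time()
    manifest: dict = {
        "config": asdict(config),
        "version": __version__,
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "counts": {},
        "findings": findings,
    }
    counts = manifest["counts"]

    try:
        # --- stage 1: preprocessing -----------------------------------
        id_map = IdMapTable.from_tsv(config.id_map)
        known = read_known_mirnas(config.known_mirnas)
        dialects = load_dialects(config.dialect_config)

        ders = []
        unmapped_mirnas: list[str] = []
        der_targets = set()
        db = None
        if config.der_list is not None:
            for raw in _read_list(config.der_list):
                hits = normalize_mirna(raw, known)
                if hits:
                    ders.extend(hits)
                else:
                    unmapped_mirnas.append(raw)
            dbs = [
                read_target_table(
                    entry["path"],
                    entry.get("dialect", "generic"),
                    id_map,
                    known,
                    dialects=dialects,
                )
                for entry in config.target_dbs
            ]
            db = combine_databases(dbs, mode=config.db_mode)
            der_targets, missing = targets_of(db, ders)
            counts["target_interactions"] = len(db)
            counts["ders"] = len(ders)
            counts["ders_without_targets"] = len(missing)
            counts["der_targets"] = len(der_targets)
        counts["unmapped_mirnas"] = len(unmapped_mirnas)

        degs = set()
        unmapped_genes: list[str] = []
        if config.deg_list is not None:
            mapping, unmapped_genes = map_symbols(_read_list(config.deg_list), id_map)
            degs = set(mapping.values())
            counts["degs"] = len(degs)
        counts["unmapped_deg_symbols"] = len(unmapped_genes)

        log.info(
            "preprocessing: %d target interactions, %d DERs, %d DEGs",
            counts.get("target_interactions", 0), counts.get("ders", 0),
            counts.get("degs", 0),
        )
        net = read_edge_list(config.ppi, dialect=config.ppi_dialect, id_map=id_map)
        counts["ppi_edges_raw"] = net.n_edges
        net = filter_top_fraction(net, config.ppi_top_fraction)
        counts["ppi_edges_kept"] = net.n_edges
        counts["ppi_nodes"] = net.n_nodes
        log.info(
            "network: kept %d/%d edges over %d nodes (top fraction %g)",
            net.n_edges, counts["ppi_edges_raw"], net.n_nodes,
            config.ppi_top_fraction,
        )

        # --- stage 2: boosting ----------------------------------------
        seed_mode = config.seed_mode
        if config.der_list is None or config.deg_list is None:
            # only one input side: intersection would be empty by construction
            seed_mode = "union"
            log.info("single input list supplied; seeds degrade to that list")
        seeds = construct_seed_set(degs, der_targets, net, mode=seed_mode)
        counts["seeds"] = len(seeds)
        counts["seed_candidates_not_in_network"] = len(seeds.dropped)

        A = build_transition_matrix(net, weighting="binary")
        u0 = make_restart_vector(seeds, net)
        scores = rwr(
            A, u0, restart_p=config.restart_p,
            tol=config.rwr_tol, max_iter=config.rwr_max_iter,
        )
        counts["rwr_iterations"] = scores.iterations
        counts["rwr_converged"] = scores.converged
        log.info(
            "propagation: %d seeds, converged=%s in %d iterations (p=%g)",
            len(seeds), scores.converged, scores.iterations, config.restart_p,
        )

        _write_seeds(seeds, out_dir / "seeds.tsv")
        _write_scores(scores, seeds, out_dir / "scores.tsv")

        boosted_by_level = {}
        for level in config.boost_levels:
            boosted = select_boosted(scores, seeds, level, net)
            boosted_by_level[level] = boosted
            n_direct, n_indirect = classify_connectivity(boosted, seeds, net)
            counts[f"boosted_{_level_tag(level)}"] = len(boosted)
            counts[f"direct_{_level_tag(level)}"] = n_direct
            counts[f"indirect_{_level_tag(level)}"] = n_indirect
            _write_boosted(boosted, seeds, scores, out_dir / f"boosted_{_level_tag(level)}.tsv")

        # --- stage 3: pathway analysis --------------------------------
        coll = read_gmt(config.gmt, id_map)
        counts["gmt_terms"] = len(coll)

        seed_query = set(seeds.genes) & coll.universe
        seed_records = (
            enrich(seed_query, coll, min_overlap=config.min_overlap)
            if seed_query
            else []
        )
        write_enrichment_table(seed_records, out_dir / "enrichment_seed.tsv")

        per_level_records = {}
        perm_rows = []
        for level, boosted in boosted_by_level.items():
            query = set(boosted.genes) & coll.universe
            records = enrich(query, coll, min_overlap=config.min_overlap) if query else []
            per_level_records[level] = records
            write_enrichment_table(records, out_dir / f"enrichment_{_level_tag(level)}.tsv")
            observed = count_enriched(
                records, config.enrichment_threshold, config.use_adjusted_p
            )
            counts[f"enriched_{_level_tag(level)}"] = observed
            log.info(
                "enrichment at level %g: %d terms below p=%g",
                level, observed, config.enrichment_threshold,
            )
            null = permutation_null(
                coll,
                set_size=len(query),
                n_perm=config.n_perm,
                threshold=config.enrichment_threshold,
                observed=observed,
                rng_seed=config.rng_seed + round(level * 1000),
                min_overlap=config.min_overlap,
            )
            perm_rows.append(
                (
                    level, observed, float(np.mean(null.null_counts)),
                    float(np.std(null.null_counts)), null.empirical_p,
                )
            )
            pd.DataFrame(
                [perm_rows[-1]],
                columns=["level", "observed", "null_mean", "null_sd", "empirical_p"],
            ).to_csv(out_dir / f"permutation_{_level_tag(level)}.tsv", sep="\t", index=False)

        sig_terms = sorted(
            {
                r.term_id
                for records in per_level_records.values()
                for r in records
                if (r.p_adjusted if config.use_adjusted_p else r.p_value)
                < config.enrichment_threshold
            }
        )
        dotplot_table(per_level_records, sig_terms).to_csv(
            out_dir / "dotplot.tsv", sep="\t", index=False, na_rep="N/A"
        )

        # hub / centrality analysis on the largest boosted subnetwork
        top_level = max(boosted_by_level) if boosted_by_level else None
        if top_level is not None:
            boosted = boosted_by_level[top_level]
            sub = induced_subnetwork(net, set(boosted.genes))
            if sub.n_edges:
                report = eigenvector_centrality(sub)
                write_centrality_table(report, out_dir / "centrality.tsv")
                hubs = find_hubs(report, "degree_top_k", config.hub_k)
                deg_map = {g.entrez: int(d) for g, d in zip(report.nodes, report.degree)}
                pd.DataFrame(
                    {
                        "entrez": [g.entrez for g in hubs],
                        "symbol": [g.symbol or "" for g in hubs],
                        "degree": [deg_map[g.entrez] for g in hubs],
                    }
                ).to_csv(out_dir / "hubs.tsv", sep="\t", index=False)
                counts["hubs"] = len(hubs)
            overlay = build_overlay(
                boosted, seeds, db, ders, net, degs=degs,
                scores=scores.by_entrez(),
            ) if db is not None else None
            if overlay is not None:
                export_graph(overlay, out_dir / "network.graphml", "graphml")
                export_graph(overlay, out_dir / "network.json", "json")
                counts["overlay_mirnas"] = len(overlay.mirna_nodes)

        manifest["runtime_seconds"] = round(time.time() - t_start, 3)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return out_dir
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_seeds(seeds, path: Path) -> None:
    rows = sorted(
        (
            g.entrez,
            g.symbol or "",
            seeds.provenance[g.entrez]["is_DEG"],
            seeds.provenance[g.entrez]["is_DER_target"],
        )
        for g in seeds.genes
    )
    pd.DataFrame(rows, columns=["entrez", "symbol", "is_DEG", "is_DER_target"]).to_csv(
        path, sep="\t", index=False
    )


def _write_scores(scores, seeds, path: Path) -> None:
    seed_entrez = seeds.entrez
    ranked = sorted(
        zip(scores.nodes, scores.scores), key=lambda gs: (-gs[1], gs[0].entrez)
    )
    rows = [
        (g.entrez, g.symbol or "", f"{float(s):.12g}", rank, g.entrez in seed_entrez)
        for rank, (g, s) in enumerate(ranked, start=1)
    ]
    pd.DataFrame(rows, columns=["entrez", "symbol", "score", "rank", "is_seed"]).to_csv(
        path, sep="\t", index=False
    )


def _write_boosted(boosted, seeds, scores, path: Path) -> None:
    seed_entrez = seeds.entrez
    score_map = scores.by_entrez()
    rows = [
        (
            g.entrez,
            g.symbol or "",
            f"{score_map[g.entrez]:.12g}",
            g.entrez in seed_entrez,
            "seed" if g.entrez in seed_entrez else boosted.classification[g.entrez],
        )
        for g in boosted.genes
    ]
    pd.DataFrame(
        rows, columns=["entrez", "symbol", "score", "is_seed", "classification"]
    ).to_csv(path, sep="\t", index=False)
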