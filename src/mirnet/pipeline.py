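"""End-to-end orchestration of the multi-omics target-identification analysis.

Stage order mirrors the experimental workflow: pull-down enrichment and
selection, transcript/protein differential selection, overlap statistics on
restricted universes (down-regulated lists only), seed-word scans over three
rankings, pathway over-representation on merged lists (both regulation
directions), and PPI network construction with hub ranking (four networks:
one per experiment plus the combined union).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import expression, netbuild, pathways, pulldown, seedscan, setstats
from .synthetic import GroundTruth, SimulationConfig, SyntheticData, simulate_all

logger = logging.getLogger("mirnet")

__all__ = ["PipelineConfig", "PipelineReport", "run_all", "evaluate_recovery"]

EXPERIMENTS = ("pulldown", "transcriptome", "proteome")


@dataclass
class PipelineConfig:
    """All stage parameters plus either a simulation config or input paths."""

    simulation: SimulationConfig | None = None
    input_paths: dict[str, str] = field(default_factory=dict)
    pseudocount: float = 1.0
    elbow_method: str = "robust_gaussian"
    k_sigma: float = 2.0
    fc_cutoff: float = 0.5
    min_peptides: int = 3
    protein_fdr: float | None = None
    scan_k: int = 7
    window_start: int = 500
    window_step: int = 500
    protein_window: int = 100
    score_min: int = 400
    top_n_hubs: int = 30
    top_n_pathways: int = 100
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and not self.input_paths:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.fc_cutoff <= 0 or self.pseudocount < 0 or self.score_min < 0:
            raise ValueError("invalid stage parameters")


@dataclass
class PipelineReport:
    """Structured result surface of one full run."""

    enrichment: pd.DataFrame
    cutoff: pulldown.CutoffEstimate
    selected: dict[str, list[str]]  # per-experiment deregulated lists
    down_lists: dict[str, list[str]]
    up_lists: dict[str, list[str]]
    universes: dict[str, list[str]]
    protein_table: pd.DataFrame
    pairwise_overlaps: dict[str, setstats.GeneSetOverlap]
    triple_regions: dict[str, int]
    common_universe_size: int
    restricted_sizes: dict[str, int]
    scan_reports: dict[str, pd.DataFrame]
    scan_results: dict[str, seedscan.WordScanResult]
    seed_words: seedscan.SeedWords
    ora_tables: dict[str, pd.DataFrame]
    merged_lists: dict[str, list[str]]
    network_comparison: pd.DataFrame
    hub_tables: dict[str, pd.DataFrame]
    manifest: dict[str, Any]


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        logger.info("simulating inputs (seed=%d)", config.simulation.seed)
        return simulate_all(config.simulation)
    p = config.input_paths
    required = {"counts", "transcriptome", "peptides", "utrs",
                "transcript_map", "network", "genesets"}
    missing = required - set(p)
    if missing:
        raise ValueError(f"missing input paths: {sorted(missing)}")
    utrs_by_tx = seedscan.read_fasta(p["utrs"])
    tx2gene = seedscan.read_transcript_map(p["transcript_map"])
    utrs, _ = seedscan.longest_utr_per_gene(utrs_by_tx, tx2gene)
    counts = pulldown.read_counts(p["counts"])
    mirna = p.get("mirna_sequence", SimulationConfig().mirna_sequence)
    return SyntheticData(
        config=SimulationConfig(seed=config.seed, mirna_sequence=mirna),
        genes=list(counts.index),
        utrs=utrs,
        counts=counts,
        transcript_fc=expression.read_fold_changes(p["transcriptome"]),
        peptides=expression.read_peptides(p["peptides"]),
        network=netbuild.read_interactions(p["network"], score_min=config.score_min),
        genesets=pathways.read_gmt(p["genesets"]),
        truth=GroundTruth(),
    )


def _ranked_utrs(order: list[str], utrs: dict[str, str], key: str) -> seedscan.RankedUtrList:
    genes = [g for g in order if g in utrs and utrs[g]]
    return seedscan.RankedUtrList(
        genes=genes, sequences=[utrs[g] for g in genes], ranking_key=key
    )


def run_all(config: PipelineConfig) -> PipelineReport:
    """Execute every stage on simulated or supplied inputs."""
    data = _load_inputs(config)
    stage = "input"
    try:
        # --- pull-down -----------------------------------------------------
        stage = "pulldown"
        counts = pulldown.filter_all_zero(data.counts)
        norm = pulldown.normalize_counts(counts)
        enr = pulldown.enrichment_ratio(norm, pseudocount=config.pseudocount)
        cutoff = pulldown.elbow_cutoff(
            enr["log2_ratio"], method=config.elbow_method, k=config.k_sigma
        )
        pd_list = pulldown.select_enriched(enr, cutoff)
        pd_universe = list(counts.index)

        # --- expression ----------------------------------------------------
        stage = "expression"
        tr_down, tr_up = expression.select_by_foldchange(
            data.transcript_fc, cutoff=config.fc_cutoff
        )
        tr_universe = list(data.transcript_fc.loc[data.transcript_fc["detected"], "gene"])
        peptides = expression.scale_normalize(data.peptides)
        prot = expression.rollup_protein(peptides, min_peptides=config.min_peptides)
        pr_down, pr_up = expression.select_proteins(
            prot, cutoff=config.fc_cutoff, fdr=config.protein_fdr
        )
        pr_universe = list(prot["protein"])

        universes = {
            "pulldown": pd_universe,
            "transcriptome": tr_universe,
            "proteome": pr_universe,
        }
        down_lists = {"pulldown": pd_list, "transcriptome": tr_down, "proteome": pr_down}
        up_lists = {"pulldown": [], "transcriptome": tr_up, "proteome": pr_up}
        # deregulated lists (both directions) feed ORA and the networks
        selected = {
            name: list(dict.fromkeys(down_lists[name] + up_lists[name]))
            for name in EXPERIMENTS
        }

        # --- overlaps on restricted universes (down-regulated only) -------
        stage = "setstats"
        pairwise: dict[str, setstats.GeneSetOverlap] = {}
        for a, b in (("pulldown", "transcriptome"), ("pulldown", "proteome"),
                     ("transcriptome", "proteome")):
            uni = sorted(set(universes[a]) & set(universes[b]))
            la = setstats.restrict_to_universe(down_lists[a], uni)
            lb = setstats.restrict_to_universe(down_lists[b], uni)
            pairwise[f"{a}_vs_{b}"] = setstats.hypergeom_overlap(la, lb, uni)
        common = sorted(set.intersection(*(set(u) for u in universes.values())))
        restricted = {
            name: setstats.restrict_to_universe(down_lists[name], common)
            for name in EXPERIMENTS
        }
        triple = setstats.triple_overlap(
            [restricted[n] for n in EXPERIMENTS], common
        )

        # --- seed-word scans ----------------------------------------------
        stage = "seedscan"
        seed_words = seedscan.derive_seed_words(data.config.mirna_sequence)
        rankings = {
            "pulldown": [g for g in enr.sort_values(
                "log2_ratio", ascending=False, kind="stable").index],
            "transcriptome": list(
                data.transcript_fc.sort_values("log2fc", kind="stable")["gene"]
            ),
            "proteome": list(prot.sort_values("log2_ratio", kind="stable")["protein"]),
        }
        scan_results: dict[str, seedscan.WordScanResult] = {}
        scan_reports: dict[str, pd.DataFrame] = {}
        for name, order in rankings.items():
            ranked = _ranked_utrs(order, data.utrs, key=name)
            win = config.protein_window if name == "proteome" else config.window_start
            step = config.protein_window if name == "proteome" else config.window_step
            win = min(win, len(ranked))
            res = seedscan.sylamer_scan(ranked, k=config.scan_k,
                                        window_start=win, window_step=step)
            scan_results[name] = res
            scan_reports[name] = seedscan.scan_report(res, seed_words)

        # --- pathway over-representation ----------------------------------
        stage = "pathways"
        merged, _prov = pathways.merge_lists(selected)
        merged_universes = dict(universes)
        if len(EXPERIMENTS) >= 3:
            for leave_out in EXPERIMENTS:
                rest = [n for n in EXPERIMENTS if n != leave_out]
                merged_universes[f"combined_minus_{leave_out}"] = sorted(
                    set().union(*(universes[n] for n in rest))
                )
        merged_universes["combined"] = sorted(
            set().union(*(universes[n] for n in EXPERIMENTS))
        )
        ora_tables = {
            name: pathways.ora(genes_, data.genesets, merged_universes[name])
            for name, genes_ in merged.items()
        }

        # --- networks ------------------------------------------------------
        stage = "netbuild"
        interactions = netbuild.clean_interactions(data.network, score_min=config.score_min)
        net_lists = {n: selected[n] for n in EXPERIMENTS}
        net_lists["combined"] = merged["combined"]
        graphs = {
            name: netbuild.induced_subnetwork(interactions, genes_)
            for name, genes_ in net_lists.items()
            if genes_
        }
        comparison = netbuild.compare_networks(graphs)
        hub_tables = {
            name: netbuild.rank_hubs(g, top_n=config.top_n_hubs)
            for name, g in graphs.items()
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = _manifest(config, data)
    report = PipelineReport(
        enrichment=enr,
        cutoff=cutoff,
        selected=selected,
        down_lists=down_lists,
        up_lists=up_lists,
        universes=universes,
        protein_table=prot,
        pairwise_overlaps=pairwise,
        triple_regions=triple,
        common_universe_size=len(common),
        restricted_sizes={k: len(v) for k, v in restricted.items()},
        scan_reports=scan_reports,
        scan_results=scan_results,
        seed_words=seed_words,
        ora_tables=ora_tables,
        merged_lists=merged,
        network_comparison=comparison,
        hub_tables=hub_tables,
        manifest=manifest,
    )
    if config.outdir:
        _write_report(report, data, config)
    return report


def _manifest(config: PipelineConfig, data) -> dict[str, Any]:
    params = dataclasses.asdict(config)
    if params.get("simulation"):
        params["simulation"] = dataclasses.asdict(config.simulation)
    return {"parameters": params, "seed": config.seed, "n_genes": len(data.genes)}


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_report(report: PipelineReport, data, config: PipelineConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.enrichment.to_csv(out / "enrichment.tsv", sep="\t")
    with open(out / "cutoff.json", "w") as fh:
        json.dump(dataclasses.asdict(report.cutoff), fh, indent=1)
    for name, genes in report.selected.items():
        (out / f"selected_{name}.txt").write_text("\n".join(genes) + "\n")
    report.protein_table.to_csv(out / "proteins.tsv", sep="\t", index=False)
    overlaps = {k: dataclasses.asdict(v) for k, v in report.pairwise_overlaps.items()}
    with open(out / "overlaps.json", "w") as fh:
        json.dump({"pairwise": overlaps, "triple_regions": report.triple_regions,
                   "common_universe_size": report.common_universe_size,
                   "restricted_sizes": report.restricted_sizes}, fh, indent=1)
    for name, rep in report.scan_reports.items():
        rep.to_csv(out / f"scan_report_{name}.tsv", sep="\t", index=False)
        report.scan_results[name].to_frame().to_csv(
            out / f"scan_landscape_{name}.tsv", sep="\t"
        )
    for name, tbl in report.ora_tables.items():
        tbl.to_csv(out / f"ora_{name}.tsv", sep="\t", index=False)
    report.network_comparison.to_csv(out / "network_comparison.tsv", sep="\t", index=False)
    for name, tbl in report.hub_tables.items():
        tbl.to_csv(out / f"hubs_{name}.tsv", sep="\t", index=False)
    if data.truth.target_genes:
        data.truth.to_json(out / "truth.json")
        metrics = evaluate_recovery(report, data.truth)
        with open(out / "recovery_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1, default=float)
    manifest = dict(report.manifest)
    manifest["files"] = {
        p.name: _hash_file(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    report.manifest = manifest


def evaluate_recovery(report: PipelineReport, truth: GroundTruth) -> dict[str, Any]:
    """Per-stage recovery of the planted structure in a synthetic run."""
    targets = set(truth.target_genes)
    if targets and not (targets & set(report.universes["pulldown"])):
        raise ValueError("truth and report gene namespaces do not overlap")

    def recall_precision(selected: list[str], relevant: set[str]) -> tuple[float, float]:
        s = set(selected)
        if not relevant:
            return float("nan"), float("nan")
        rec = len(s & relevant) / len(relevant)
        prec = len(s & relevant) / len(s) if s else float("nan")
        return rec, prec

    metrics: dict[str, Any] = {}
    for name in ("pulldown", "transcriptome"):
        rec, prec = recall_precision(report.down_lists[name], targets)
        metrics[f"{name}_recall"] = rec
        metrics[f"{name}_precision"] = prec
    detectable = targets & set(report.universes["proteome"])
    rec, prec = recall_precision(report.down_lists["proteome"], detectable)
    metrics["proteome_recall"] = rec
    metrics["proteome_precision"] = prec
    metrics["proteome_detectable_targets"] = len(detectable)

    for name, rep in report.scan_reports.items():
        seed_rows = rep.loc[rep["is_seed_match"]]
        metrics[f"seed_word_best_rank_{name}"] = (
            int(seed_rows["rank"].min()) if len(seed_rows) else None
        )
    metrics["triple_overlap_count"] = report.triple_regions["abc"]

    hubs = set(truth.hub_genes)
    if hubs and "combined" in report.hub_tables:
        tbl = report.hub_tables["combined"]
        top = set(tbl.loc[tbl["rank"] <= len(hubs), "gene"])
        metrics["hub_recovery_rate"] = len(top & hubs) / len(hubs)
        top2 = set(tbl.loc[tbl["rank"] <= 2 * len(hubs), "gene"])
        metrics["hub_recovery_rate_top2n"] = len(top2 & hubs) / len(hubs)
    comp = report.network_comparison.set_index("network")["mean_neighbors"]
    if "combined" in comp.index:
        singles = comp.drop("combined")
        metrics["combined_mean_neighbors"] = float(comp["combined"])
        metrics["max_single_mean_neighbors"] = float(singles.max())
        metrics["combined_most_connected"] = bool(comp["combined"] > singles.max())
    return metrics
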