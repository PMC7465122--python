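"""End-to-end orchestration of the six analysis stages.

Stages run in order meta_deg -> gcn -> ppi_cluster -> enrichment_hub -> ffl ->
survival, reading the file-based inputs named in a :class:`PipelineConfig`
and writing every stage's outputs plus a machine-readable ``summary.json``
into a run directory. Every threshold default is the analysis default the
package documents, so a bare run is the reference pipeline. Completed stages
are detected by a sentinel file and skipped on rerun (delete the run
directory for a fresh run).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, ffl, gcn, io as cio, meta_deg, ppi, survival

log = logging.getLogger("coexffl.pipeline")

STAGES = ["meta_deg", "gcn", "ppi_cluster", "enrichment_hub", "ffl", "survival"]


@dataclass
class PipelineConfig:
    """Input paths and thresholds for a full run."""

    expr: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)
    ppi_edges: str = ""
    gmt: list[str] = field(default_factory=list)
    mirna_gene: str = ""
    tf_gene: str = ""
    mirna_tf: str = ""
    tier1: str = ""
    mouse_tables: list[str] = field(default_factory=list)
    survival_table: str = ""
    out_dir: str = "runs/latest"

    alpha_meta: float = 1e-4
    fc: float = 1.5
    r2_target: float = 0.80
    min_module_size: int = 30
    deep_split: int = 2
    merge_height: float = 0.2
    mm_threshold: float = 0.9
    kme_floor: float = 0.7
    string_threshold: float = 0.9
    enrich_alpha: float = 0.001
    mirna_score: float = 0.95
    tf_p: float = 0.001
    conserve_targets: str = "all"
    enrich_universe: str = "library"  # "library" union or "genes" (all input genes)
    seed: int = 0

    def validate(self) -> None:
        if len(self.expr) < 2 or len(self.expr) != len(self.samples):
            raise ValueError("need >=2 expression matrices with matching sample sheets")
        for path in [*self.expr, *self.samples, self.ppi_edges, *self.gmt,
                     self.mirna_gene, self.tf_gene, self.mirna_tf, self.tier1,
                     *self.mouse_tables, self.survival_table]:
            if path and not Path(path).exists():
                raise FileNotFoundError(path)
        for name, lo, hi in [
            ("alpha_meta", 0, 1), ("enrich_alpha", 0, 1), ("mirna_score", 0, 1),
            ("tf_p", 0, 1), ("string_threshold", 0, 1), ("merge_height", 0, 2),
            ("mm_threshold", 0, 1), ("kme_floor", 0, 1), ("r2_target", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _done(run_dir: Path, stage: str) -> Path:
    return run_dir / f".{stage}.done"


def run_all(config: PipelineConfig) -> Path:
    """Execute all stages, resuming past any stage whose sentinel exists."""
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    summary: dict = {"stages": {}}
    summary_path = run_dir / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())

    def checkpoint(stage: str) -> None:
        _done(run_dir, stage).write_text("done\n")
        summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")

    try:
        # ---- meta_deg -------------------------------------------------
        deg_path = run_dir / "meta_degs.tsv"
        if not _done(run_dir, "meta_deg").exists():
            datasets = [cio.read_paired_set(e, s) for e, s in zip(config.expr, config.samples)]
            res = meta_deg.run_meta_deg(datasets, alpha=config.alpha_meta, fc_threshold=config.fc)
            res.table.to_csv(deg_path, sep="\t", index_label="gene", float_format="%.6g")
            summary["stages"]["meta_deg"] = {
                "n_genes_tested": int(len(res.table)),
                **res.counts,
            }
            checkpoint("meta_deg")
        degs = pd.read_csv(deg_path, sep="\t", index_col=0)
        deg_genes = sorted(degs.index[degs["class"] != "not_significant"])

        # ---- gcn ------------------------------------------------------
        rep_path = run_dir / "representative_genes.txt"
        if not _done(run_dir, "gcn").exists():
            if len(deg_genes) < 3:
                raise RuntimeError("stage gcn: too few meta-DEGs to build a network")
            datasets = [cio.read_paired_set(e, s) for e, s in zip(config.expr, config.samples)]
            merged = pd.concat(
                [meta_deg.ensure_log2(ds.expr).loc[deg_genes] for ds in datasets], axis=1
            )
            model = gcn.build_coexpression_network(
                merged,
                target_r2=config.r2_target,
                min_module_size=config.min_module_size,
                deep_split=config.deep_split,
                merge_height=config.merge_height,
                mm_threshold=config.mm_threshold,
                kme_floor=config.kme_floor,
            )
            model.connectivity.to_csv(run_dir / "module_assignment.tsv", sep="\t", float_format="%.6g")
            model.eigengenes.to_csv(run_dir / "eigengenes.tsv", sep="\t", float_format="%.6g")
            cio.write_gene_list(model.representative_genes_flat, rep_path)
            sizes = model.partition.labels.value_counts().to_dict()
            summary["stages"]["gcn"] = {
                "beta": int(model.beta),
                "reached_r2_target": bool(model.soft_threshold.reached_target),
                "module_sizes": {str(k): int(v) for k, v in sizes.items()},
                "n_representative": len(model.representative_genes_flat),
            }
            checkpoint("gcn")

        # ---- ppi_cluster ---------------------------------------------
        cluster_path = run_dir / "mcode_clusters.tsv"
        top_path = run_dir / "top_cluster_genes.txt"
        if not _done(run_dir, "ppi_cluster").exists():
            graph = ppi.load_edges(config.ppi_edges, score_threshold=config.string_threshold)
            result = ppi.mcode_find_clusters(graph, ppi.MCODEParams())
            ppi.write_clusters(result, cluster_path)
            if result.top is None:
                raise RuntimeError("stage ppi_cluster: no dense cluster found")
            cio.write_gene_list(result.top.nodes, top_path)
            ppi.write_top_cluster_graphml(graph, result, run_dir / "top_cluster.graphml")
            summary["stages"]["ppi_cluster"] = {
                "n_network_nodes": graph.number_of_nodes(),
                "n_network_edges": graph.number_of_edges(),
                "n_clusters": len(result.clusters),
                "top_cluster_nodes": len(result.top.nodes),
                "top_cluster_edges": result.top.n_edges,
                "top_cluster_score": round(result.top.score, 3),
            }
            checkpoint("ppi_cluster")
        top_genes = cio.read_gene_list(top_path)

        # ---- enrichment_hub ------------------------------------------
        hub_path = run_dir / "hub_genes.txt"
        if not _done(run_dir, "enrichment_hub").exists():
            universe = None
            if config.enrich_universe == "genes":
                universe = set(degs.index.astype(str))
                universe |= set(top_genes)
            results = []
            for gmt_path in config.gmt:
                library = cio.read_gmt(gmt_path)
                res = enrichment.enrich(
                    top_genes, library, library_name=Path(gmt_path).stem, universe=universe
                )
                res.table.to_csv(run_dir / f"enrichment_{res.library}.tsv", sep="\t", float_format="%.6g")
                results.append(res)
            hubs = enrichment.hub_genes(results, top_genes, alpha=config.enrich_alpha)
            cio.write_gene_list(sorted(hubs), hub_path)
            summary["stages"]["enrichment_hub"] = {
                "n_significant_terms": int(
                    sum(len(r.significant(config.enrich_alpha)) for r in results)
                ),
                "hub_genes": sorted(hubs),
            }
            checkpoint("enrichment_hub")
        hubs = cio.read_gene_list(hub_path)

        # ---- ffl ------------------------------------------------------
        if not _done(run_dir, "ffl").exists():
            tables = [cio.read_edge_table(p) for p in (config.mirna_gene, config.tf_gene, config.mirna_tf)]
            mouse = [cio.read_edge_table(p) for p in config.mouse_tables]
            tier1 = cio.read_gene_list(config.tier1)
            filtered = ffl.filter_edges(tables, mirna_score=config.mirna_score, tf_p=config.tf_p)
            screened = ffl.two_tier_screen(
                filtered, tier1, mouse,
                mirna_score=config.mirna_score, tf_p=config.tf_p,
                conserve_targets=config.conserve_targets,
            )
            network = ffl.assemble_network(screened)
            network.summary_table().to_csv(run_dir / "ffl_summary.tsv", sep="\t", index=False)
            if network.n_edges:
                ffl.write_sif(network, run_dir / "ffl_network.sif")
                ffl.write_graphml(network, run_dir / "ffl_network.graphml")
            motif = ffl.highest_order_motif(network)
            summary["stages"]["ffl"] = {
                "n_nodes": network.n_nodes,
                "n_edges": network.n_edges,
                "edge_type_counts": network.edge_type_counts(),
                "motif": None
                if motif is None
                else {
                    "mirna": motif.mirna,
                    "tfs": list(motif.tfs),
                    "gene": motif.gene,
                    "order": motif.order,
                },
            }
            checkpoint("ffl")

        # ---- survival -------------------------------------------------
        if not _done(run_dir, "survival").exists():
            table = cio.read_survival_table(config.survival_table)
            rows = []
            for gene in hubs:
                if gene not in table.columns:
                    log.warning("survival: no expression column for %s; skipped", gene)
                    continue
                res = survival.analyze_gene(table, gene)
                rows.append(res.to_dict())
                low = res.curves["low"].curve.assign(cohort="low")
                high = res.curves["high"].curve.assign(cohort="high")
                pd.concat([low, high]).to_csv(
                    run_dir / f"km_{gene}.tsv", sep="\t", index=False, float_format="%.6g"
                )
            out = pd.DataFrame(rows)
            out.to_csv(run_dir / "survival_results.tsv", sep="\t", index=False, float_format="%.6g")
            summary["stages"]["survival"] = {
                "genes_analyzed": [r["gene"] for r in rows],
                "results": rows,
            }
            checkpoint("survival")
    except Exception as exc:  # annotate with the failing stage
        done = {s for s in STAGES if _done(run_dir, s).exists()}
        stage = next((s for s in STAGES if s not in done), "unknown")
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    _write_report(summary, run_dir / "report.md")
    return run_dir


def _write_report(summary: dict, path: Path) -> None:
    lines = ["# Pipeline run report", ""]
    for stage in STAGES:
        info = summary["stages"].get(stage)
        if info is None:
            continue
        lines.append(f"## {stage}")
        for k, v in info.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    path.write_text("\n".join(lines))
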