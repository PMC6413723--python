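"""End-to-end pipeline chaining all analysis stages on one input bundle.

Differential expression runs first; its up/down calls feed set enrichment,
TFBS enrichment, network hub detection, CMap drug ranking, qPCR
concordance and the cross-species comparison.  Stages whose inputs are
missing are skipped with a logged notice.  Every run writes a manifest
echoing the resolved configuration and seed, sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cmap, cross_species, de_analysis, enrichment, io_formats, network, qpcr, tfbs

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and thresholds; defaults are the analysis' standard values
    (fold change > 2, p < 0.05, PWM relative score 0.9, TF alpha 0.01,
    minimum edge score 0.4, set-enrichment FDR 0.05, 1000 permutations)."""

    out_dir: str
    expression: str | None = None
    ct_values: str | None = None
    gmt: str | None = None
    promoters: str | None = None
    pwms: str | None = None
    edges: str | None = None
    profiles: str | None = None
    human_de: str | None = None
    orthologs: str | None = None
    fc_cutoff: float = 2.0
    p_cutoff: float = 0.05
    rel_score: float = 0.9
    tf_alpha: float = 0.01
    min_edge_score: float = 0.4
    go_fdr: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    adjust: str = "none"
    alpha: float | None = None
    reference_gene: str = qpcr.DEFAULT_REFERENCE_GENE

    def validate(self) -> None:
        if self.expression is None:
            raise ValueError("an expression table is required (all stages depend on DE calls)")
        for thr, lo, hi in (
            ("p_cutoff", 0, 1),
            ("rel_score", 0, 1),
            ("tf_alpha", 0, 1),
            ("min_edge_score", 0, 1),
            ("go_fdr", 0, 1),
        ):
            v = getattr(self, thr)
            if not lo <= v <= hi:
                raise ValueError(f"{thr} must lie in [{lo}, {hi}], got {v}")
        if self.fc_cutoff <= 0:
            raise ValueError("fc_cutoff must be > 0")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages for which inputs are present; return a result dict
    and write per-stage TSV/JSON outputs plus ``manifest.json``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    skipped: list[str] = []

    matrix = io_formats.read_table(config.expression, "expression")
    de_table = de_analysis.call_de(
        matrix,
        fc_cutoff=config.fc_cutoff,
        p_cutoff=config.p_cutoff,
        adjust=config.adjust,
        alpha=config.alpha,
    )
    de_table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    up = set(de_table.loc[de_table["direction"] == "up", "gene_id"])
    down = set(de_table.loc[de_table["direction"] == "down", "gene_id"])
    background = set(de_table["gene_id"])
    results["de"] = {"n_up": len(up), "n_down": len(down), "n_genes": len(background)}

    if config.ct_values:
        ct = io_formats.read_table(config.ct_values, "ct_values")
        genes = sorted(set(ct["gene_id"]) - {config.reference_gene})
        fc_q = {g: qpcr.ddct_fold_change(ct, g, config.reference_gene) for g in genes}
        fc_r = dict(zip(de_table["gene_id"], de_table["fold_change"]))
        conc = qpcr.concordance({g: fc_r[g] for g in genes if g in fc_r}, fc_q)
        conc.per_gene.to_csv(out / "qpcr_concordance.tsv", sep="\t", index=False)
        results["qpcr"] = {"n": conc.n, "r": conc.r, "p_value": conc.p_value}
    else:
        skipped.append("qpcr")

    if config.gmt:
        annotation = io_formats.read_gmt(config.gmt)
        enr = enrichment.enrich_sets(up | down, background, annotation, fdr_cutoff=config.go_fdr)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        results["enrichment"] = {"n_terms_tested": len(enr),
                                 "n_significant": int(enr["significant"].sum()) if len(enr) else 0}
    else:
        skipped.append("enrichment")

    if config.promoters and config.pwms:
        promoters = io_formats.read_fasta(config.promoters)
        spwms = [tfbs.score_pwm(p) for p in io_formats.read_pwm_library(config.pwms)]
        tf_table = tfbs.tf_enrichment(
            up, down, background, promoters, spwms,
            cutoff=config.rel_score, alpha=config.tf_alpha,
        )
        tf_table.to_csv(out / "tf_enrichment.tsv", sep="\t", index=False)
        results["tfbs"] = {
            "n_enriched_up": int(((tf_table["direction"] == "up") & tf_table["enriched"]).sum()),
            "n_enriched_down": int(((tf_table["direction"] == "down") & tf_table["enriched"]).sum()),
        }
    else:
        skipped.append("tfbs")

    if config.edges:
        net = io_formats.read_table(config.edges, "edges")
        filtered = network.filter_edges(net, min_score=config.min_edge_score)
        stats = network.degree_stats(filtered)
        stats.degree_of_node.rename_axis("gene_id").reset_index().to_csv(
            out / "degrees.tsv", sep="\t", index=False
        )
        results["network"] = {
            "n_nodes": len(stats.degree_of_node),
            "n_edges": filtered.n_edges,
            "mean_degree": stats.mean,
            "sd_degree": stats.sd,
            "hub_threshold": stats.threshold,
            "hubs": stats.hubs,
            "powerlaw_slope": stats.powerlaw_slope,
        }
    else:
        skipped.append("network")

    if config.profiles:
        profiles = io_formats.read_table(config.profiles, "ranked_profile")
        ranking = cmap.rank_drugs(profiles, up, down, n_perm=config.n_perm, seed=config.seed)
        ranking.to_csv(out / "cmap_ranking.tsv", sep="\t", index=False)
        results["cmap"] = {
            "top_drug": ranking["drug_id"].iloc[0],
            "top_score": float(ranking["score"].iloc[0]),
            "top_perm_p": float(ranking["perm_p"].iloc[0]),
        }
    else:
        skipped.append("cmap")

    if config.human_de and config.orthologs:
        human = io_formats.read_table(config.human_de, "de_table")
        orthologs = io_formats.read_table(config.orthologs, "ortholog_map")
        mouse = de_table.loc[de_table["direction"] != "unchanged", ["gene_id", "log2fc", "p_value"]]
        ov = cross_species.overlap(mouse.reset_index(drop=True), human, orthologs)
        counts, pairs = cross_species.classify(ov.shared)
        pairs.to_csv(out / "cross_species.tsv", sep="\t", index=False)
        results["cross_species"] = {
            "shared": len(ov.shared),
            "mouse_only": len(ov.mouse_only),
            "human_only": len(ov.human_only),
            **counts,
        }
    else:
        skipped.append("cross_species")

    for stage in skipped:
        logger.info("stage %s skipped: inputs not provided", stage)
    results["skipped"] = skipped

    manifest = {"config": dataclasses.asdict(config), "stages_run": sorted(set(results) - {"skipped"})}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "results.json").write_text(json.dumps(results, indent=2, default=str))
    return results
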