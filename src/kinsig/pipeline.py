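"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes: (optional) simulation -> ingestion and
filtering -> per-gene statistics -> class comparisons -> co-expression
bootstrap -> deleterious-mutation enrichment -> relatedness estimation,
writing machine-readable outputs (TSV for tables, JSON for nested
results) plus a log that accounts for every filter (sites and genes in
and out), so the usual "after filtering, N SNPs / M genes" bookkeeping
can be reproduced on any input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, coexpression, enrichment, genome_io, group_compare
from . import popgen, relatedness as relatedness_mod

logger = logging.getLogger("kinsig.pipeline")

STATS_COLUMNS = [
    "gene_id", "category", "trait_group", "n_samples", "effective_length",
    "S", "singletons", "pi", "pi_N", "pi_S", "pi_N_over_pi_S", "tajimas_D",
    "fu_li_D_star", "fu_li_F_star", "fu_li_D", "fu_li_F",
    "Pn", "Ps", "Dn", "Ds", "mk_p", "NI", "DoS", "Ka", "Ks", "Ka_over_Ks",
]


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one pipeline run."""

    vcf: str
    gff: str
    fasta: str
    out_dir: str
    outgroup_fasta: str | None = None
    outgroup_vcf: str | None = None
    expression: str | None = None
    categories: str | None = None
    min_call_rate: float = 0.8
    min_mapped_fraction: float = 0.5
    drop_indels: bool = True
    test_family: dict = field(default_factory=dict)
    coexpression_set: str = "cooperative+private"
    bootstrap_B: int = 10_000
    mk_min_derived_freq: float = 0.15
    relatedness_site_class: str = "nonsynonymous"
    seed: int = 0

    def __post_init__(self) -> None:
        for t in ("min_call_rate", "min_mapped_fraction"):
            if not 0 <= getattr(self, t) <= 1:
                raise ValueError(f"{t} must be in [0, 1]")
        if not self.drop_indels:
            raise ValueError(
                "drop_indels=false is not supported: population-genetic "
                "statistics are defined on SNPs only"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _comparison_to_dict(res: group_compare.ComparisonResult) -> dict:
    return {
        "variable": res.variable,
        "family": res.family,
        "statistic": res.statistic,
        "df": list(res.df),
        "p_value": res.p_value,
        "posthoc": None if res.posthoc is None else res.posthoc.to_dict("records"),
        "group_summaries": res.group_summaries.reset_index()
        .rename(columns={"index": "group"})
        .to_dict("records"),
        "n_dropped_missing": res.n_dropped_missing,
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the result bundle to ``config.out_dir``.

    Any stage failure aborts with the stage name; outputs of completed
    stages are left on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("kinsig")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    paths: dict[str, Path] = {"log": log_path}
    stage = "ingest"
    try:
        logger.info("kinsig %s starting; seed=%d", __version__, config.seed)
        reference = genome_io.read_fasta(config.fasta)
        samples, records = genome_io.read_vcf(config.vcf)
        genes = genome_io.read_gff(config.gff, contigs=reference.keys())
        if config.categories:
            genome_io.apply_categories(genes, genome_io.read_categories(config.categories))
        logger.info("ingested %d variant records, %d genes, %d strains",
                    len(records), len(genes), len(samples))

        stage = "filter"
        filt = genome_io.filter_variants(records, config.min_call_rate,
                                         drop_indels=config.drop_indels)
        logger.info(
            "site filter: %d SNPs kept, %d dropped below call rate %.2f, "
            "%d indels set aside", len(filt.snps), filt.n_dropped_low_call,
            config.min_call_rate, len(filt.indels),
        )
        kept_genes = genome_io.filter_genes(genes, config.min_mapped_fraction)
        logger.info("gene filter: %d of %d genes kept (mapped fraction >= %.2f)",
                    len(kept_genes), len(genes), config.min_mapped_fraction)

        stage = "outgroup"
        outgroup = None
        if config.outgroup_fasta:
            outgroup = genome_io.read_fasta(config.outgroup_fasta)
        elif config.outgroup_vcf:
            _, og_records = genome_io.read_vcf(config.outgroup_vcf)
            outgroup = genome_io.build_outgroup_pseudogenome(reference, og_records)

        stage = "stats"
        alignments = [
            genome_io.build_alignment(g, filt.snps, reference, samples, outgroup)
            for g in kept_genes
        ]
        table = popgen.compute_stats_table(alignments, kept_genes)
        table = table[[c for c in STATS_COLUMNS if c in table.columns]]
        paths["gene_stats"] = out / "gene_stats.tsv"
        table.to_csv(paths["gene_stats"], sep="\t", index=False,
                     float_format="%.10g")
        logger.info("computed statistics for %d genes", len(table))

        stage = "compare"
        comparisons = []
        for variable in ("pi", "pi_N", "pi_S", "Ka", "Ks"):
            family = config.test_family.get(variable)
            try:
                res = group_compare.compare_classes(table, variable, family=family)
            except ValueError as exc:
                logger.warning("comparison for %s skipped: %s", variable, exc)
                continue
            comparisons.append(_comparison_to_dict(res))
        paths["comparisons"] = out / "comparisons.json"
        paths["comparisons"].write_text(json.dumps(comparisons, indent=2))

        stage = "coexpression"
        if config.expression:
            matrix = coexpression.median_normalize(
                coexpression.read_expression(config.expression))
            cats = {g.gene_id: g.category for g in kept_genes}
            wanted = set(config.coexpression_set.split("+"))
            candidate = [g for g in matrix.gene_ids if cats.get(g) in wanted]
            if len(candidate) >= 2:
                boot = coexpression.bootstrap_null(
                    matrix, candidate, B=config.bootstrap_B, seed=config.seed)
                paths["bootstrap"] = out / "coexpression_null.tsv"
                pd.DataFrame({"null_mean_rho": boot.null_means}).to_csv(
                    paths["bootstrap"], sep="\t", index=False)
                paths["coexpression"] = out / "coexpression.json"
                paths["coexpression"].write_text(json.dumps({
                    "set_size": len(candidate),
                    "num_pairs": len(candidate) * (len(candidate) - 1) // 2,
                    "rho_observed": boot.rho_obs,
                    "B": boot.B,
                    "percentile": boot.percentile,
                    "p_value": boot.p_value,
                }, indent=2))
                logger.info("co-expression: rho=%.3f percentile=%.1f p=%.4g",
                            boot.rho_obs, boot.percentile, boot.p_value)

        stage = "enrichment"
        deleterious = genome_io.annotate_deleterious(
            filt.snps + filt.indels, kept_genes, reference)
        paths["deleterious"] = out / "deleterious.tsv"
        deleterious.to_csv(paths["deleterious"], sep="\t")
        enrich_out = {}
        for mode in ("gene_presence", "mutation_count"):
            try:
                res = enrichment.enrichment_test(deleterious, kept_genes, mode=mode)
            except ValueError as exc:
                logger.warning("enrichment (%s) skipped: %s", mode, exc)
                continue
            enrich_out[mode] = dataclasses.asdict(res)
        paths["enrichment"] = out / "enrichment.json"
        paths["enrichment"].write_text(json.dumps(enrich_out, indent=2))

        stage = "relatedness"
        rel_out = {}
        for site_class in ("nonsynonymous", "all_sites"):
            try:
                est = relatedness_mod.estimate_relatedness(
                    table, site_class=site_class, seed=config.seed)
            except ValueError as exc:
                logger.warning("relatedness (%s) skipped: %s", site_class, exc)
                continue
            rel_out[site_class] = dataclasses.asdict(est)
            logger.info("relatedness (%s): r_hat=%.3f [%.3f, %.3f]",
                        site_class, est.r_hat_raw, est.ci_low, est.ci_high)
        paths["relatedness"] = out / "relatedness.json"
        paths["relatedness"].write_text(json.dumps(rel_out, indent=2))
        logger.info("pipeline complete")
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return paths
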