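"""End-to-end orchestration: the stages behind the CLI subcommands.

Each stage is a function from validated inputs to result tables; the CLI adds
file plumbing, config handling and run manifests on top.  ``run_full`` chains
everything in memory and is what the test-suite and the analysis scripts use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import association, diffexpr, enrichment_network, integration, meta
from .data_io import CountMatrix, GeneSetCollection, TargetDB, log_cpm

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = [
    diffexpr.Contrast("SR60_vs_SR40", "SR60", "SR40"),
    diffexpr.Contrast("SR70_vs_SR50", "SR70", "SR50"),
]


@dataclass
class PipelineResult:
    """Everything the full pipeline produced, stage by stage."""

    mirna_de: pd.DataFrame
    gene_de: pd.DataFrame
    mirna_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    aa_mirnas: pd.DataFrame
    aa_mirnas_discordant: pd.DataFrame
    aa_genes: pd.DataFrame
    aa_genes_discordant: pd.DataFrame
    correlations: pd.DataFrame
    pairs: pd.DataFrame
    enrichment: pd.DataFrame
    pathway: pd.DataFrame | None
    network: object
    counts: dict = field(default_factory=dict)


def run_de_meta(
    cm: CountMatrix,
    samples: pd.DataFrame,
    contrasts=None,
    dispersion_method: str = "cox_reid_grid",
    fixed_phi: float | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Two-set differential expression followed by Fisher meta-analysis."""
    contrasts = contrasts or DEFAULT_CONTRASTS
    de = diffexpr.run_two_set_de(
        cm, samples, contrasts,
        dispersion_method=dispersion_method, fixed_phi=fixed_phi,
        prior_count=prior_count,
    )
    return meta.build_meta_table(de)


def run_full(
    mirna_cm: CountMatrix,
    gene_cm: CountMatrix,
    samples: pd.DataFrame,
    targetdb: TargetDB,
    gene_sets: GeneSetCollection | None = None,
    contrasts=None,
    rule: meta.SelectionRule = meta.SelectionRule(),
    thresholds: integration.PairThresholds = integration.PairThresholds(),
    dispersion_method: str = "cox_reid_grid",
    fixed_phi: float | None = None,
    prior_count: float = 0.5,
    alias: dict | None = None,
) -> PipelineResult:
    """The full integrative analysis on in-memory inputs.

    miRNAs are selected on nominal significance in both contrasts with
    direction consistency; genes on the meta FDR with direction consistency;
    all (AA-miRNA x gene) correlations are computed on logCPM; the
    three-condition rule defines valid pairs, classified direct/indirect
    against the target database; per-miRNA target enrichment and (when gene
    sets are given) pathway ORA of the network genes complete the run.
    """
    contrasts = contrasts or DEFAULT_CONTRASTS
    mirna_meta_tbl = run_de_meta(
        mirna_cm, samples, contrasts, dispersion_method, fixed_phi, prior_count
    )
    gene_meta_tbl = run_de_meta(
        gene_cm, samples, contrasts, dispersion_method, fixed_phi, prior_count
    )
    aa_mirnas, aa_mir_disc = meta.select_aa_features(mirna_meta_tbl, rule, "nominal_both")
    aa_genes, aa_gene_disc = meta.select_aa_features(gene_meta_tbl, rule, "fdr_meta")

    counts = {
        "n_mirna_tested": len(mirna_meta_tbl),
        "n_gene_tested": len(gene_meta_tbl),
        "n_aa_mirna": len(aa_mirnas),
        "n_aa_gene": len(aa_genes),
    }

    if len(aa_mirnas) == 0:
        logger.warning("no age-associated miRNAs selected; downstream stages empty")
        empty_pairs = pd.DataFrame(
            columns=["mirna", "gene", "r", "n", "p_cor", "mirna_direction",
                     "gene_direction", "interaction", "type_label"]
        )
        return PipelineResult(
            mirna_de=mirna_meta_tbl, gene_de=gene_meta_tbl,
            mirna_meta=mirna_meta_tbl, gene_meta=gene_meta_tbl,
            aa_mirnas=aa_mirnas, aa_mirnas_discordant=aa_mir_disc,
            aa_genes=aa_genes, aa_genes_discordant=aa_gene_disc,
            correlations=pd.DataFrame(columns=["mirna", "gene", "r", "n", "p_cor"]),
            pairs=empty_pairs, enrichment=pd.DataFrame(), pathway=None,
            network=enrichment_network.build_network(empty_pairs), counts=counts,
        )

    mirna_expr = log_cpm(mirna_cm, prior_count=0.5)
    gene_expr = log_cpm(gene_cm, prior_count=0.5)
    mirna_sel_expr = type(mirna_expr)(mirna_expr.values.loc[list(aa_mirnas["feature"])])
    correlations = association.correlate_all(mirna_sel_expr, gene_expr)
    counts["n_correlations"] = len(correlations)
    counts["n_cor_significant"] = int((correlations["p_cor"] < thresholds.p_cor).sum())

    pairs_raw, n_unannotated = integration.valid_pairs(
        aa_mirnas, aa_genes, correlations, thresholds, alias=alias
    )
    counts["n_pairs_excluded_unannotated"] = n_unannotated
    pairs = integration.classify_pairs(pairs_raw, targetdb)
    counts["n_valid_pairs"] = len(pairs)
    counts["n_direct"] = int((pairs["interaction"] == "direct").sum())
    counts["n_indirect"] = int((pairs["interaction"] == "indirect").sum())

    universe = len(gene_meta_tbl)
    enrichment = integration.enrichment_table(
        list(aa_mirnas["feature"]), correlations, targetdb,
        set(aa_genes["feature"]), universe, thresholds.p_cor,
    )

    pathway = None
    if gene_sets is not None and len(pairs) > 0:
        gene_col = "gene_id" if "gene_id" in pairs.columns else "gene"
        query = set(pairs[gene_col])
        tested = set(gene_meta_tbl["feature"])
        universe_genes = set().union(*gene_sets.sets.values()) & tested
        if query & universe_genes:
            pathway = enrichment_network.ora(query, gene_sets, universe_genes)

    network = enrichment_network.build_network(pairs)
    counts["n_network_nodes"] = network.number_of_nodes()
    counts["n_network_edges"] = network.number_of_edges()
    logger.info("pipeline counts: %s", counts)

    return PipelineResult(
        mirna_de=mirna_meta_tbl, gene_de=gene_meta_tbl,
        mirna_meta=mirna_meta_tbl, gene_meta=gene_meta_tbl,
        aa_mirnas=aa_mirnas, aa_mirnas_discordant=aa_mir_disc,
        aa_genes=aa_genes, aa_genes_discordant=aa_gene_disc,
        correlations=correlations, pairs=pairs, enrichment=enrichment,
        pathway=pathway, network=network, counts=counts,
    )
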