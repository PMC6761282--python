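"""Valid miRNA-mRNA pair calling, direct/indirect classification, enrichment.

A pair of an age-associated miRNA and an age-associated gene is *valid* when
(i) the gene passes the meta FDR cut, (ii) their expression correlation is
nominally significant, and (iii) the correlation sign equals the product of
the two age-effect signs (a miRNA and gene moving the same way with age must
be positively correlated, opposite ways negatively).  A valid pair is a
*direct* interaction when the gene is a database-predicted target of the
miRNA AND the correlation is negative (the repression signature); every other
valid pair is *indirect*.  Database-predicted pairs with positive correlation
are flagged ``predicted_positive`` for transparency but remain indirect.

Target-set enrichment asks whether a miRNA's predicted targets overlap the
age-associated gene list more than chance, via the upper-tail hypergeometric
test with fold change (k/n) / (K/N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import TargetDB

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairThresholds:
    p_cor: float = 0.05
    fdr_gene: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_cor", "fdr_gene"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def _sign(x: float) -> int:
    return -1 if x < 0 else 1


def valid_pairs(
    aa_mirnas: pd.DataFrame,
    aa_genes: pd.DataFrame,
    correlations: pd.DataFrame,
    thresholds: PairThresholds = PairThresholds(),
    alias: dict | None = None,
) -> tuple[pd.DataFrame, int]:
    """Apply the three-condition valid-pair rule.

    Parameters
    ----------
    aa_mirnas
        Selected age-associated miRNAs; needs columns ``feature, logFC1,
        p_fisher`` (direction taken from logFC1 after consistency filtering).
    aa_genes
        Selected age-associated genes; needs ``feature, logFC1, p_fisher, fdr``.
    correlations
        Output of :func:`atrimir.association.correlate_all`; must cover every
        (aa miRNA, aa gene) combination — a missing pair is an upstream error.
    alias
        Optional id -> display-name map; genes absent from it are excluded
        from the output and counted (second return value), emulating
        annotation loss.

    Returns
    -------
    (pairs, n_excluded_unannotated)
    """
    mir = aa_mirnas.set_index("feature")
    gen = aa_genes.set_index("feature")
    cols = ["mirna", "gene", "r", "n", "p_cor"]
    sub = correlations[
        correlations["mirna"].isin(mir.index) & correlations["gene"].isin(gen.index)
    ][cols]
    expected = len(mir.index) * len(gen.index)
    if len(sub) < expected:
        raise ValueError(
            f"correlations cover {len(sub)} of {expected} candidate pairs; "
            "rerun the correlation stage over all selected features"
        )
    rows = []
    n_unannotated = 0
    for rec in sub.itertuples(index=False):
        g = gen.loc[rec.gene]
        m = mir.loc[rec.mirna]
        if g["fdr"] >= thresholds.fdr_gene:          # condition (i)
            continue
        if rec.p_cor >= thresholds.p_cor:            # condition (ii)
            continue
        if rec.r == 0:
            logger.warning("pair %s/%s has r exactly 0; rejected", rec.mirna, rec.gene)
            continue
        sm, sg = _sign(m["logFC1"]), _sign(g["logFC1"])
        if _sign(rec.r) != sm * sg:                  # condition (iii)
            continue
        if alias is not None and rec.gene not in alias:
            n_unannotated += 1
            continue
        rows.append(
            {
                "mirna": rec.mirna,
                "gene": alias[rec.gene] if alias is not None else rec.gene,
                "gene_id": rec.gene,
                "r": rec.r,
                "n": rec.n,
                "p_cor": rec.p_cor,
                "mirna_direction": "+" if sm > 0 else "-",
                "gene_direction": "+" if sg > 0 else "-",
                "p_fisher_mirna": m["p_fisher"],
                "p_fisher_gene": g["p_fisher"],
                "fdr_gene": g["fdr"],
            }
        )
    if n_unannotated:
        logger.info("valid_pairs: %d pairs excluded (gene not annotated)", n_unannotated)
    pairs = pd.DataFrame(
        rows,
        columns=[
            "mirna", "gene", "gene_id", "r", "n", "p_cor", "mirna_direction",
            "gene_direction", "p_fisher_mirna", "p_fisher_gene", "fdr_gene",
        ],
    )
    logger.info("valid_pairs: %d candidate pairs -> %d valid", len(sub), len(pairs))
    return pairs, n_unannotated


def classify_pairs(
    pairs: pd.DataFrame, targetdb: TargetDB, validated_only: bool = False
) -> pd.DataFrame:
    """Label each valid pair direct/indirect and assign its correlation type.

    direct  <=>  (mirna, gene) predicted in the database AND r < 0.
    ``type_label`` encodes the age directions: e.g. miRNA up and gene down is
    ``up-down`` (so a direct repression pair is up-down or down-up).
    """
    db_pairs = targetdb.pair_set() if not validated_only else {
        (m, g)
        for m, g in zip(
            targetdb.records.loc[targetdb.records["evidence"] == "validated", "mirna"],
            targetdb.records.loc[targetdb.records["evidence"] == "validated", "gene"],
        )
    }
    word = {"+": "up", "-": "down"}
    out = pairs.copy()
    in_db = [
        (m, g) in db_pairs
        for m, g in zip(out["mirna"], out.get("gene_id", out["gene"]))
    ]
    out["in_target_db"] = in_db
    out["interaction"] = np.where(out["in_target_db"] & (out["r"] < 0), "direct", "indirect")
    out["predicted_positive"] = out["in_target_db"] & (out["r"] > 0)
    out["type_label"] = [
        f"{word[md]}-{word[gd]}" for md, gd in zip(out["mirna_direction"], out["gene_direction"])
    ]
    # the sign-consistency invariant must hold on everything we emit
    sign_ok = np.sign(out["r"]) == [
        (1 if md == "+" else -1) * (1 if gd == "+" else -1)
        for md, gd in zip(out["mirna_direction"], out["gene_direction"])
    ]
    if not bool(np.all(sign_ok)):
        raise AssertionError("sign-consistency invariant violated in classified pairs")
    logger.info(
        "classify_pairs: %d direct, %d indirect (%d predicted_positive)",
        int((out["interaction"] == "direct").sum()),
        int((out["interaction"] == "indirect").sum()),
        int(out["predicted_positive"].sum()),
    )
    return out


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) drawing n from a population N containing K successes."""
    if not (0 <= k <= min(n, K)) and k != 0:
        raise ValueError("k out of range")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def target_enrichment(
    mirna_id: str,
    targets: set,
    aa_genes: set,
    universe_size: int,
    scope: str = "direct",
) -> dict:
    """Hypergeometric enrichment of one miRNA's target set in the AA-gene list.

    fold_change = (k/|targets|) / (|aa_genes|/N).  An empty target set yields
    fold_change 0, p 1, flagged ``empty_targets``.
    """
    K = len(aa_genes)
    n = len(targets)
    if n > universe_size or K > universe_size:
        raise ValueError("target or AA-gene set larger than the universe")
    if n == 0:
        return {
            "mirna": mirna_id, "scope": scope, "n_targets": 0, "k": 0,
            "K": K, "N": universe_size, "fold_change": 0.0, "p_hyper": 1.0,
            "empty_targets": True,
        }
    k = len(targets & aa_genes)
    fc = (k / n) / (K / universe_size) if K > 0 else 0.0
    return {
        "mirna": mirna_id, "scope": scope, "n_targets": n, "k": k,
        "K": K, "N": universe_size, "fold_change": fc,
        "p_hyper": hypergeom_upper_tail(k, universe_size, K, n),
        "empty_targets": False,
    }


def enrichment_table(
    aa_mirnas: list,
    correlations: pd.DataFrame,
    targetdb: TargetDB,
    aa_genes: set,
    universe_size: int,
    p_cor_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA direct/indirect target-set enrichment vs the AA-gene list.

    Computed genome-wide from the full correlation table: the *direct* scope
    of a miRNA is its database-predicted targets that are significantly
    negatively correlated with it (the repression signature applied before
    any age filter); the *indirect* scope is the significantly correlated
    genes that are not predicted targets.  Each scope is tested for
    over-representation of the age-associated genes.
    """
    rows = []
    for mirna in sorted(aa_mirnas):
        predicted = targetdb.targets_of(mirna)
        sub = correlations[correlations["mirna"] == mirna]
        sig = sub[sub["p_cor"] < p_cor_threshold]
        direct = set(sig.loc[sig["r"] < 0, "gene"]) & predicted
        indirect = set(sig["gene"]) - predicted
        rows.append(target_enrichment(mirna, direct, aa_genes, universe_size, "direct"))
        rows.append(target_enrichment(mirna, indirect, aa_genes, universe_size, "indirect"))
    return pd.DataFrame(rows)
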