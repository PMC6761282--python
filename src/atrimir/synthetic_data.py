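"""Coupled miRNA/mRNA count simulator with known ground truth.

Emulates the study design the pipeline assumes: 12 samples in four age groups
(SR40/SR50/SR60/SR70, three samples each, one F and two M per group),
negative-binomial counts (variance = mean + phi * mean^2, the edgeR
convention) with sample-specific library sizes, a subset of features carrying
monotone age-dependent log2 fold changes, and planted miRNA -> target
repression couplings in which a target gene's mean is multiplied by
2^(-coupling * centred latent miRNA log2 CPM) — the coupling acts on the
regulator's noiseless latent abundance so the ground truth stays well
defined.  The target database contains every planted pair plus uniformly
sampled decoys.  All randomness flows from the single config seed.

Planted effects are parameterised per decade-pair contrast: an age-associated
feature changes by ``planted_logfc`` log2 units between the groups of each
reciprocal contrast (SR60 vs SR40, SR70 vs SR50), i.e. half that per decade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CountMatrix,
    GeneSetCollection,
    TargetDB,
    write_count_matrix,
    write_gmt,
    write_table,
    write_target_db,
)

GROUP_AGES = {"SR40": 40, "SR50": 50, "SR60": 60, "SR70": 70}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults mirror the emulated study's dimensions."""

    n_per_group: int = 3
    groups: tuple = ("SR40", "SR50", "SR60", "SR70")
    n_mirna: int = 1482
    n_gene: int = 23346
    phi: float = 0.1
    libsize_range: tuple = (8e5, 1.2e6)   # log-uniform per-sample totals
    n_aa_mirna: int = 20
    n_aa_gene: int = 80
    planted_logfc: float = 2.0
    n_direct_pairs: int = 30
    coupling_strength: float = 0.8
    decoy_factor: int = 10
    baseline_median_cpm: float = 50.0
    baseline_sigma_ln: float = 1.2
    #: couplings attach only to regulators/targets with baseline CPM at or
    #: above this floor (default: the population median), so every planted
    #: repression signature is actually expressed and hence measurable;
    #: a coupling on a ~zero-count feature would be undetectable by
    #: construction and would test nothing
    coupling_min_cpm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_aa_mirna > self.n_mirna or self.n_aa_gene > self.n_gene:
            raise ValueError("more planted features than features")
        if self.n_direct_pairs > self.n_gene - self.n_aa_gene:
            raise ValueError("not enough non-AA genes to host planted couplings")
        if self.n_direct_pairs > 0 and self.n_aa_mirna == 0:
            raise ValueError("planted couplings require planted AA-miRNAs")
        if self.phi < 0 or self.n_per_group < 1:
            raise ValueError("phi must be >= 0 and n_per_group >= 1")


@dataclass
class GroundTruth:
    """What was planted: ids, directions, couplings and latent means."""

    aa_mirna_directions: dict      # mirna id -> +1 / -1
    aa_gene_directions: dict       # explicitly planted AA genes -> +1 / -1
    coupled_gene_directions: dict  # repression targets -> effective sign
    direct_pairs: set              # {(mirna, gene)}
    mirna_latent_logcpm: pd.DataFrame  # noiseless log2 CPM per sample
    true_logfc_mirna: dict
    true_logfc_gene: dict
    mirna_expected_mean: pd.DataFrame | None = None  # NB mean per cell
    gene_expected_mean: pd.DataFrame | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with variance mean + phi * mean^2; phi = 0 degrades to Poisson."""
    mean = np.maximum(mean, 1e-12)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate(config: SimulationConfig, noise_replicate: int | None = None):
    """Generate (mirna CountMatrix, gene CountMatrix, sample table, TargetDB,
    GroundTruth), fully deterministic given ``config.seed``.

    ``noise_replicate`` redraws only the count noise (a fresh NB realisation
    around the same latent means, library sizes and planted truth), which is
    what a sequencing replicate of the same tissue panel would look like;
    the default ``None`` ties the noise to the config seed as well.
    """
    ss = np.random.SeedSequence(config.seed)
    structure_seed, noise_seed = ss.spawn(2)
    rng = np.random.default_rng(structure_seed)
    if noise_replicate is None:
        rng_noise = np.random.default_rng(noise_seed)
    else:
        rng_noise = np.random.default_rng(
            np.random.SeedSequence(entropy=(config.seed, int(noise_replicate)))
        )
    groups = list(config.groups)
    n_samples = config.n_per_group * len(groups)
    sample_ids = [f"S{i+1:02d}" for i in range(n_samples)]
    sample_groups = [g for g in groups for _ in range(config.n_per_group)]
    ages = [GROUP_AGES[g] for g in sample_groups]
    # one female, remainder male per group (the emulated design has 1F + 2M)
    sexes = [("F" if i == 0 else "M") for g in groups for i in range(config.n_per_group)]
    sample_table = pd.DataFrame(
        {"sample_id": sample_ids, "group": sample_groups, "age": ages, "sex": sexes}
    )
    age_index = np.array([groups.index(g) for g in sample_groups], dtype=float)

    mirna_ids = [f"mir-{i+1:04d}" for i in range(config.n_mirna)]
    gene_ids = [f"GENE{i+1:05d}" for i in range(config.n_gene)]

    def baselines(n: int) -> np.ndarray:
        return config.baseline_median_cpm * np.exp(
            rng.normal(0.0, config.baseline_sigma_ln, size=n)
        )

    mirna_base = baselines(config.n_mirna)
    gene_base = baselines(config.n_gene)

    aa_mirna_idx = rng.choice(config.n_mirna, size=config.n_aa_mirna, replace=False)
    aa_gene_idx = rng.choice(config.n_gene, size=config.n_aa_gene, replace=False)
    mirna_signs = rng.choice([-1, 1], size=config.n_aa_mirna)
    gene_signs = rng.choice([-1, 1], size=config.n_aa_gene)

    # per-decade slope so each reciprocal contrast (two decades apart) sees
    # the full planted_logfc
    slope = config.planted_logfc / 2.0

    def latent_cpm(base: np.ndarray, idx: np.ndarray, signs: np.ndarray) -> np.ndarray:
        """Noiseless CPM per feature x sample before coupling."""
        lf = np.zeros((len(base), n_samples))
        lf[idx, :] = np.outer(signs * slope, age_index)
        return base[:, None] * 2.0 ** lf

    mirna_cpm = latent_cpm(mirna_base, aa_mirna_idx, mirna_signs)
    mirna_latent_logcpm = pd.DataFrame(
        np.log2(mirna_cpm), index=mirna_ids, columns=sample_ids
    )

    gene_cpm = latent_cpm(gene_base, aa_gene_idx, gene_signs)

    # repression couplings: targets drawn from expressed genes (baseline at or
    # above the coupling floor) that are not planted AA genes; regulators
    # cycle through the expressed AA-miRNAs
    floor = (
        config.coupling_min_cpm
        if config.coupling_min_cpm is not None
        else config.baseline_median_cpm
    )
    free_genes = np.setdiff1d(np.arange(config.n_gene), aa_gene_idx)
    eligible_genes = free_genes[gene_base[free_genes] >= floor]
    if len(eligible_genes) < config.n_direct_pairs:
        eligible_genes = free_genes  # degenerate floor: fall back to all
    coupled_gene_idx = rng.choice(
        eligible_genes, size=config.n_direct_pairs, replace=False
    )
    eligible_mirnas = aa_mirna_idx[mirna_base[aa_mirna_idx] >= floor]
    if len(eligible_mirnas) == 0 and config.n_direct_pairs > 0:
        eligible_mirnas = aa_mirna_idx
    regulators = np.array(
        [eligible_mirnas[i % len(eligible_mirnas)] for i in range(config.n_direct_pairs)],
        dtype=int,
    )
    direct_pairs = set()
    coupled_dirs = {}
    true_logfc_gene = {gene_ids[i]: float(gene_signs[j] * config.planted_logfc)
                       for j, i in enumerate(aa_gene_idx)}
    for gi, mi in zip(coupled_gene_idx, regulators):
        latent = np.log2(mirna_cpm[mi, :])
        centred = latent - latent.mean()
        gene_cpm[gi, :] = gene_cpm[gi, :] * 2.0 ** (-config.coupling_strength * centred)
        direct_pairs.add((mirna_ids[mi], gene_ids[gi]))
        mi_pos = int(np.where(aa_mirna_idx == mi)[0][0])
        eff_sign = -int(mirna_signs[mi_pos])
        coupled_dirs[gene_ids[gi]] = eff_sign
        true_logfc_gene[gene_ids[gi]] = float(
            -config.coupling_strength * mirna_signs[mi_pos] * config.planted_logfc
        )

    def draw_counts(cpm: np.ndarray, ids: list[str]) -> tuple[CountMatrix, pd.DataFrame]:
        lo, hi = config.libsize_range
        libs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
        means = cpm * libs[None, :] / 1e6
        counts = _nb_draw(rng_noise, means, config.phi)
        return (
            CountMatrix(pd.DataFrame(counts, index=ids, columns=sample_ids), feature_kind="gene"),
            pd.DataFrame(means, index=ids, columns=sample_ids),
        )

    mirna_cm, mirna_means = draw_counts(mirna_cpm, mirna_ids)
    mirna_cm.feature_kind = "miRNA"
    gene_cm, gene_means = draw_counts(gene_cpm, gene_ids)

    # decoy target-db pairs: AA-miRNA x uncoupled gene, uniform without
    # replacement, decoy_factor per planted pair
    n_decoys = (
        config.decoy_factor * max(config.n_direct_pairs, 1)
        if config.n_aa_mirna > 0
        else 0
    )
    decoy_gene_pool = np.setdiff1d(np.arange(config.n_gene), coupled_gene_idx)
    decoys = set()
    while len(decoys) < n_decoys:
        mi = mirna_ids[aa_mirna_idx[rng.integers(config.n_aa_mirna)]]
        gi = gene_ids[decoy_gene_pool[rng.integers(len(decoy_gene_pool))]]
        if (mi, gi) not in direct_pairs:
            decoys.add((mi, gi))
    all_pairs = sorted(direct_pairs) + sorted(decoys)
    targetdb = TargetDB(
        pd.DataFrame(
            {
                "mirna": [m for m, _ in all_pairs],
                "gene": [g for _, g in all_pairs],
                "source": "sim",
                "evidence": "predicted",
            }
        )
    )

    truth = GroundTruth(
        aa_mirna_directions={mirna_ids[i]: int(s) for i, s in zip(aa_mirna_idx, mirna_signs)},
        aa_gene_directions={gene_ids[i]: int(s) for i, s in zip(aa_gene_idx, gene_signs)},
        coupled_gene_directions=coupled_dirs,
        direct_pairs=direct_pairs,
        mirna_latent_logcpm=mirna_latent_logcpm,
        true_logfc_mirna={mirna_ids[i]: float(s * config.planted_logfc)
                          for i, s in zip(aa_mirna_idx, mirna_signs)},
        true_logfc_gene=true_logfc_gene,
        mirna_expected_mean=mirna_means,
        gene_expected_mean=gene_means,
    )
    return mirna_cm, gene_cm, sample_table, targetdb, truth


def make_gene_sets(
    gene_ids: list,
    truth: GroundTruth,
    rng: np.random.Generator,
    n_sets: int = 10,
    set_size: int = 40,
) -> GeneSetCollection:
    """Small synthetic pathway collection: random sets plus one enriched in
    the planted age-associated genes (a positive control for ORA)."""
    sets, desc = {}, {}
    aa = sorted(set(truth.aa_gene_directions) | set(truth.coupled_gene_directions))
    n_aa_members = min(len(aa), set_size // 2)
    enriched = set(rng.choice(aa, size=n_aa_members, replace=False))
    filler = rng.choice(gene_ids, size=set_size - len(enriched), replace=False)
    sets["AGING_SET"] = enriched | set(filler)
    desc["AGING_SET"] = "synthetic set enriched in planted age-associated genes"
    for i in range(n_sets - 1):
        sets[f"RANDOM_SET_{i+1:02d}"] = set(
            rng.choice(gene_ids, size=set_size, replace=False)
        )
        desc[f"RANDOM_SET_{i+1:02d}"] = "synthetic random gene set"
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_fixture(bundle, directory, gene_sets: GeneSetCollection | None = None) -> list:
    """Write a simulated bundle as the exact TSV/GMT inputs the CLI consumes,
    plus ground-truth tables.  Returns the written paths."""
    mirna_cm, gene_cm, sample_table, targetdb, truth = bundle
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []

    def _p(name: str) -> Path:
        p = directory / name
        paths.append(p)
        return p

    write_count_matrix(mirna_cm, _p("mirna_counts.tsv"))
    write_count_matrix(gene_cm, _p("gene_counts.tsv"))
    write_table(sample_table, _p("samples.tsv"))
    write_target_db(targetdb, _p("targets.tsv"))
    truth_features = pd.DataFrame(
        [
            {"feature": f, "kind": "miRNA", "direction": d,
             "true_logfc": truth.true_logfc_mirna[f], "coupled": False}
            for f, d in sorted(truth.aa_mirna_directions.items())
        ]
        + [
            {"feature": f, "kind": "gene", "direction": d,
             "true_logfc": truth.true_logfc_gene[f], "coupled": False}
            for f, d in sorted(truth.aa_gene_directions.items())
        ]
        + [
            {"feature": f, "kind": "gene", "direction": d,
             "true_logfc": truth.true_logfc_gene[f], "coupled": True}
            for f, d in sorted(truth.coupled_gene_directions.items())
        ]
    )
    write_table(truth_features, _p("truth_features.tsv"))
    write_table(
        pd.DataFrame(sorted(truth.direct_pairs), columns=["mirna", "gene"]),
        _p("truth_direct_pairs.tsv"),
    )
    if gene_sets is not None:
        write_gmt(gene_sets, _p("gene_sets.gmt"))
    return paths
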