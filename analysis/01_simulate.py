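"""Generate the study-scale synthetic dataset the downstream analyses consume.

Emulates the design the pipeline targets: 12 samples in four age groups
(3 per group, 1F/2M), 1,482 miRNAs and 23,346 genes with NB counts
(phi = 0.1), 10 planted age-associated miRNAs and 60 genes (logFC 2 per
contrast), and 12 miRNA->target repression couplings (strength 0.8) plus a
10x decoy target database.  Everything is written as TSV/GMT under
results/data/ together with the ground-truth tables.
"""

import pathlib

import numpy as np

from atrimir.synthetic_data import SimulationConfig, make_gene_sets, simulate, write_fixture

ROOT = pathlib.Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "data"

CONFIG = SimulationConfig(
    n_aa_mirna=10,
    n_aa_gene=60,
    n_direct_pairs=12,
    seed=7,
)

if __name__ == "__main__":
    bundle = simulate(CONFIG)
    gene_sets = make_gene_sets(
        bundle[1].feature_ids, bundle[4], np.random.default_rng(CONFIG.seed + 1)
    )
    paths = write_fixture(bundle, OUT, gene_sets=gene_sets)
    truth = bundle[4]
    print(f"simulated {CONFIG.n_mirna} miRNAs x {CONFIG.n_gene} genes, 12 samples")
    print(f"planted: {len(truth.aa_mirna_directions)} AA-miRNAs, "
          f"{len(truth.aa_gene_directions)} AA-genes, "
          f"{len(truth.direct_pairs)} repression couplings")
    for p in paths:
        print(" ", p.relative_to(ROOT))
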