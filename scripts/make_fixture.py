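"""Regenerate the committed tiny fixture under tests/data/tiny.

The fixture is a 50-miRNA x 500-gene simulated bundle (seed 42) with 6
planted age-associated miRNAs, 20 planted age-associated genes and 8
repression couplings, plus a small synthetic GMT collection.  Running this
script twice produces byte-identical files; the test-suite asserts the
committed copy matches.
"""

from pathlib import Path

import numpy as np

from atrimir.synthetic_data import SimulationConfig, make_gene_sets, simulate, write_fixture

TINY_CONFIG = SimulationConfig(
    n_mirna=50,
    n_gene=500,
    n_aa_mirna=6,
    n_aa_gene=20,
    n_direct_pairs=8,
    seed=42,
)


def build(directory) -> list:
    bundle = simulate(TINY_CONFIG)
    rng = np.random.default_rng(TINY_CONFIG.seed + 1)
    gene_sets = make_gene_sets(bundle[1].feature_ids, bundle[4], rng)
    return write_fixture(bundle, directory, gene_sets=gene_sets)


if __name__ == "__main__":
    out = Path(__file__).resolve().parent.parent / "tests" / "data" / "tiny"
    for p in build(out):
        print(p)
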