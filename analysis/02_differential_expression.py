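"""Two-set NB-GLM differential expression for miRNAs and genes.

For each matrix, estimates a common Cox-Reid dispersion per contrast and runs
the likelihood-ratio test for SR60 vs SR40 and SR70 vs SR50, writing the
aligned per-feature table (logFC, logCPM, LR, p for both contrasts) under
results/tables/.
"""

import pathlib

from atrimir.data_io import read_count_matrix, read_sample_table, write_table
from atrimir.diffexpr import run_two_set_de
from atrimir.pipeline import DEFAULT_CONTRASTS

ROOT = pathlib.Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"

if __name__ == "__main__":
    TABLES.mkdir(parents=True, exist_ok=True)
    samples = read_sample_table(DATA / "samples.tsv")
    for kind, fname in (("miRNA", "mirna_counts.tsv"), ("gene", "gene_counts.tsv")):
        cm = read_count_matrix(DATA / fname, kind)
        de = run_two_set_de(cm, samples, DEFAULT_CONTRASTS)
        out = TABLES / f"de_{'mirna' if kind == 'miRNA' else 'gene'}.tsv"
        write_table(de, out)
        n_sig1 = int((de["pvalue1"] < 0.05).sum())
        n_sig2 = int((de["pvalue2"] < 0.05).sum())
        print(f"{kind}: {len(de)} features tested; "
              f"{n_sig1} at p<0.05 in SR60 vs SR40, {n_sig2} in SR70 vs SR50 "
              f"-> {out.relative_to(ROOT)}")
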