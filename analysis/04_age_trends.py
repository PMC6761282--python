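"""Linear age trends of the selected age-associated features.

Ordinary least squares of logCPM on age in years, with 95% confidence bounds
on the slope — the secondary per-feature check that selected features change
monotonically across the four age groups rather than in one contrast only.
"""

import pathlib

from atrimir.association import trend_table
from atrimir.data_io import ExpressionMatrix, log_cpm, read_count_matrix, read_sample_table, read_table, write_table

ROOT = pathlib.Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"

if __name__ == "__main__":
    samples = read_sample_table(DATA / "samples.tsv")
    for kind, fname in (("mirna", "mirna_counts.tsv"), ("gene", "gene_counts.tsv")):
        selected = read_table(TABLES / f"aa_{kind}.tsv")
        if selected.empty:
            print(f"{kind}: nothing selected, skipping trends")
            continue
        cm = read_count_matrix(DATA / fname, "miRNA" if kind == "mirna" else "gene")
        expr = log_cpm(cm)
        sub = ExpressionMatrix(expr.values.loc[list(selected["feature"])])
        trends = trend_table(sub, samples)
        write_table(trends, TABLES / f"trend_{kind}.tsv")
        n_sig = int((trends["p_trend"] < 0.05).sum())
        print(f"{kind}: {n_sig}/{len(trends)} selected features with a "
              f"significant linear age trend (p < 0.05)")
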