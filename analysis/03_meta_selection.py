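"""Fisher meta-analysis of the two contrasts and AA-feature selection.

miRNAs are selected on nominal significance in both contrasts with consistent
direction (the conservative two-set rule); genes on BH FDR < 0.05 of the
Fisher-combined p with consistent direction.  Direction-discordant features
that pass the other filters are written to separate reports, and planted
truth is compared where available.
"""

import pathlib

import pandas as pd

from atrimir.data_io import read_table, write_table
from atrimir.meta import SelectionRule, build_meta_table, select_aa_features

ROOT = pathlib.Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"

if __name__ == "__main__":
    truth = pd.read_csv(DATA / "truth_features.tsv", sep="\t")
    rule = SelectionRule()
    for kind, mode in (("mirna", "nominal_both"), ("gene", "fdr_meta")):
        de = read_table(TABLES / f"de_{kind}.tsv")
        table = build_meta_table(de)
        selected, discordant = select_aa_features(table, rule, mode)
        write_table(table, TABLES / f"meta_{kind}.tsv")
        write_table(selected, TABLES / f"aa_{kind}.tsv")
        write_table(discordant, TABLES / f"aa_{kind}_discordant.tsv")
        planted = set(
            truth.loc[(truth["kind"] == ("miRNA" if kind == "mirna" else "gene"))
                      & ~truth["coupled"], "feature"]
        )
        hit = len(planted & set(selected["feature"]))
        print(f"{kind}: {len(selected)} selected ({mode}), "
              f"{len(discordant)} discordant; "
              f"planted recovery {hit}/{len(planted)}")
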