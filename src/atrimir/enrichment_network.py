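"""Pathway over-representation analysis and miRNA-mRNA network export.

ORA is the standard hypergeometric upper-tail test of a query gene list
against each supplied gene set, with BH adjustment across sets (shared with
the meta module, so the two stages can never disagree on the adjustment).
The interaction network is a bipartite graph of miRNA and gene nodes carrying
age direction, edge correlation sign and direct/indirect labels, exported as
SIF (three whitespace-separated tokens per line) or GraphML for Cytoscape.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .data_io import GeneSetCollection
from .integration import hypergeom_upper_tail
from .meta import bh_adjust

logger = logging.getLogger(__name__)


def ora(
    query_genes: set,
    sets: GeneSetCollection,
    universe: set,
    min_overlap: int = 0,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each gene set.

    Genes outside the universe are dropped (logged); an empty query after
    intersection is an error.  Sets are intersected with the universe too.
    BH-adjusted q-values are computed across all tested sets; the output is
    sorted by p then set id so ties break deterministically.
    """
    dropped = query_genes - universe
    if dropped:
        logger.info("ora: %d query genes outside the universe dropped", len(dropped))
    query = query_genes & universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    N = len(universe)
    K = len(query)
    rows = []
    for set_id in sets:
        members = sets.sets[set_id] & universe
        k = len(members & query)
        n = len(members)
        p = 1.0 if n == 0 else hypergeom_upper_tail(k, N, K, n)
        rows.append(
            {
                "set_id": set_id,
                "description": sets.descriptions.get(set_id, ""),
                "k": k,
                "n_set": n,
                "K": K,
                "N": N,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out[out["k"] >= min_overlap]
    return out.sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)


def build_network(pairs: pd.DataFrame) -> nx.Graph:
    """Bipartite miRNA-gene graph from classified interaction pairs.

    Node attributes: ``kind`` (miRNA/gene), ``direction`` (up/down with age).
    Edge attributes: ``sign`` (+/- of r), ``interaction`` (direct/indirect).
    Duplicate (mirna, gene) rows collapse to one edge (logged).
    """
    g = nx.Graph()
    word = {"+": "up", "-": "down"}
    n_dup = 0
    for rec in pairs.itertuples(index=False):
        if g.has_edge(rec.mirna, rec.gene):
            n_dup += 1
            continue
        g.add_node(rec.mirna, kind="miRNA", direction=word[rec.mirna_direction])
        g.add_node(rec.gene, kind="gene", direction=word[rec.gene_direction])
        g.add_edge(
            rec.mirna,
            rec.gene,
            sign="-" if rec.r < 0 else "+",
            interaction=rec.interaction,
        )
    if n_dup:
        logger.info("build_network: collapsed %d duplicate pairs", n_dup)
    return g


def export_network(g: nx.Graph, path, fmt: str = "SIF") -> None:
    """Write the network as SIF (``mirna <interaction> gene``) or GraphML."""
    fmt = fmt.upper()
    if fmt == "SIF":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                mirna, gene = (u, v) if g.nodes[u]["kind"] == "miRNA" else (v, u)
                fh.write(f"{mirna}\t{data['interaction']}\t{gene}\n")
    elif fmt == "GRAPHML":
        nx.write_graphml(g, path, infer_numeric_types=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}; use SIF or GraphML")


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
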