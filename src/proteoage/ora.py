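"""Over-representation analysis against stacked gene-set collections.

Gene sets (GO, KEGG, Reactome, Hallmark — stacked into one collection) are
mapped to UniProt space through an explicit protein-gene mapping, intersected
with the measured panel (the background), and tested with upper-tail
hypergeometric tests. BH correction is applied once across the whole stacked
collection. The rich factor is the observed/expected overlap ratio
k / (K * n / N).
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import GeneSetCollection, ValidationError, strip_isoform
from .clustering import hypergeom_sf
from .diffexp import bh_adjust

logger = logging.getLogger(__name__)


def run_ora(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    mapping: pd.DataFrame,
    min_size: int = 5,
    max_size: int = 2000,
    top: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within ``background``.

    Parameters
    ----------
    query, background : sets of UniProt accessions; query must be a subset
        of background (the measured panel).
    mapping : DataFrame with columns uniprot, gene_symbol. Many-to-many
        mappings are allowed; a protein contributes once per gene set.
    min_size, max_size : gene-set size bounds after background intersection.
    top : if given, return only the ``top`` rows by adjusted p value.
    """
    query = {strip_isoform(q) for q in query}
    background = {strip_isoform(b) for b in background}
    if not query <= background:
        raise ValidationError("query must be a subset of the background panel")

    mapping = mapping.assign(uniprot=mapping["uniprot"].map(strip_isoform))
    gene_to_prot: dict[str, set[str]] = {}
    for uniprot, gene in zip(mapping["uniprot"], mapping["gene_symbol"]):
        if uniprot in background:
            gene_to_prot.setdefault(gene, set()).add(uniprot)
    mapped_prot = set().union(*gene_to_prot.values()) if gene_to_prot else set()
    unmapped_query = len(query - mapped_prot)
    if unmapped_query:
        logger.info("%d query proteins have no gene mapping", unmapped_query)
    if not (query & mapped_prot):
        raise ValidationError("no query proteins could be mapped to gene symbols")

    N = len(background)
    n = len(query)
    rows = []
    for set_name, (db_tag, genes) in collection.items():
        set_prot = set().union(*(gene_to_prot.get(g, set()) for g in genes))
        K = len(set_prot)
        if not min_size <= K <= max_size:
            continue
        k = len(query & set_prot)
        expected = K * n / N
        rows.append(
            {
                "set_name": set_name,
                "database": db_tag,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "rich_factor": k / expected if expected > 0 else 0.0,
                "p_raw": hypergeom_sf(k, N, K, n),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "database", "k", "K", "n", "N",
                     "rich_factor", "p_raw", "p_adj"]
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table = table.sort_values(["p_adj", "p_raw", "set_name"]).reset_index(drop=True)
    if top is not None:
        table = table.head(top)
    return table
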