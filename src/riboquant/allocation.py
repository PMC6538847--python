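"""Proteome resource allocation: priority-ranked functional categories.

Genes may be annotated to several functional (KEGG-style) categories; for
resource accounting each gene must be counted once. Categories are ranked
by a user-supplied priority order and every gene keeps only its
highest-priority label; unannotated genes fall into ``"unknown"``. The
category fractions are then sums of footprint fractions phi_i.
"""

from __future__ import annotations

import pandas as pd

UNKNOWN = "unknown"


def assign_categories(gene_category_pairs, priority_order) -> dict[str, str]:
    """Map each gene to its single highest-priority category.

    ``gene_category_pairs`` is an iterable of (gene, category); a gene
    may appear with several categories. Any category not present in
    ``priority_order`` is an error.
    """
    rank = {cat: i for i, cat in enumerate(priority_order)}
    best: dict[str, str] = {}
    missing = sorted({cat for _, cat in gene_category_pairs if cat not in rank})
    if missing:
        raise ValueError(f"categories missing from priority order: {missing}")
    for gene, cat in gene_category_pairs:
        if gene not in best or rank[cat] < rank[best[gene]]:
            best[gene] = cat
    return best


def category_fractions(synth_table: pd.DataFrame,
                       assignment: dict[str, str]) -> pd.Series:
    """Fraction of ribosome footprints per category: sum of phi_i.

    Genes absent from the assignment are counted under ``"unknown"``;
    fractions sum to one exactly because phi does.
    """
    cats = synth_table.index.map(lambda g: assignment.get(g, UNKNOWN))
    fractions = synth_table["phi"].groupby(cats).sum()
    fractions.index.name = "category"
    fractions.name = "fraction"
    return fractions.sort_values(ascending=False)


def read_category_table(path) -> list[tuple[str, str]]:
    """Read a two-column TSV (locus_tag, category) into pairs."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["locus_tag", "category"], dtype=str)
    return list(df.itertuples(index=False, name=None))
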