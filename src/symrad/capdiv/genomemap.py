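"""Genomic context of reference-anchored loci and inter-locus spacing."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..loci.catalog import LocusCatalog
from ..simdata.reference import ReferenceGenome


def locus_genome_map(
    catalog: LocusCatalog,
    ref: ReferenceGenome,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-locus feature context and all within-scaffold pairwise distances.

    Returns (table, distances): the table has one row per reference-anchored
    locus (scaffold, position, strand, overlapping gene/product or empty);
    ``distances`` collects |start_i - start_j| for every locus pair sharing a
    scaffold, suitable for histogramming.
    """
    rows = []
    for locus in catalog.loci:
        if locus.anchor is None:
            continue
        scaffold, pos, strand = locus.anchor
        gene = product = ""
        for feat in ref.features_on(scaffold):
            if feat.start <= pos <= feat.end:
                gene, product = feat.gene, feat.product
                break
        rows.append(
            {"locus_id": locus.locus_id, "scaffold": scaffold, "pos": pos,
             "strand": strand, "gene": gene, "product": product}
        )
    table = pd.DataFrame(rows)
    dists: list[int] = []
    if len(table):
        for _, group in table.groupby("scaffold"):
            starts = group["pos"].to_numpy()
            for i in range(len(starts)):
                for j in range(i + 1, len(starts)):
                    dists.append(int(abs(starts[i] - starts[j])))
    return table, np.array(dists, dtype=int)
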