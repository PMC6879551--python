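"""First-SNP-per-locus diploid genotype calling from a de novo catalog."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import LocusCatalog

logger = logging.getLogger(__name__)


def call_host_snps(
    catalog: LocusCatalog,
    populations: dict[str, str] | pd.Series,
    maf_min: float = 0.05,
    presence_min_per_pop: float = 0.70,
) -> pd.DataFrame:
    """Diploid 0/1/2 genotypes at the leftmost SNP of each qualifying locus.

    Per locus the leftmost polymorphic column is the SNP; a sample's
    genotype counts its minor alleles there (one haplotype at the locus
    means homozygote; more than two haplotypes means missing, logged).
    Loci are dropped when monomorphic, when observed in fewer than
    ``presence_min_per_pop`` of any population's samples, or when the minor
    allele frequency among non-missing chromosomes is below ``maf_min``.
    Returns samples x loci DataFrame with NaN for missing.
    """
    populations = pd.Series(dict(populations))
    samples = list(populations.index)
    columns = {}
    excess_haplotypes = 0
    for locus in catalog.loci:
        seqs = locus.haplotype_seqs()
        if len(seqs) < 2:
            continue  # monomorphic
        length = len(seqs[0])
        snp_col = next(
            (j for j in range(length) if len({s[j] for s in seqs}) > 1), None
        )
        if snp_col is None:
            continue

        calls = {}
        for sample in samples:
            haps = locus.samples.get(sample)
            if not haps:
                continue
            if len(haps) > 2:
                excess_haplotypes += 1
                continue
            hap_seqs = [seq for seq, _ in haps]
            if len(hap_seqs) == 1:
                hap_seqs = hap_seqs * 2  # homozygote
            calls[sample] = (hap_seqs[0][snp_col], hap_seqs[1][snp_col])

        # presence per population
        called = pd.Series({s: s in calls for s in samples})
        presence_ok = all(
            called[populations == pop].mean() >= presence_min_per_pop
            for pop in populations.unique()
        )
        if not presence_ok:
            continue

        counts: dict[str, int] = {}
        for a1, a2 in calls.values():
            for a in (a1, a2):
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        if total == 0 or len(counts) < 2:
            continue  # monomorphic among the called samples
        minor = min(counts, key=lambda a: (counts[a], a))
        if counts[minor] / total < maf_min:
            continue
        columns[locus.locus_id] = pd.Series(
            {
                s: float((a1 == minor) + (a2 == minor))
                for s, (a1, a2) in calls.items()
            }
        )
    if excess_haplotypes:
        logger.info("%d sample-locus calls had >2 haplotypes; set missing",
                    excess_haplotypes)
    if not columns:
        return pd.DataFrame(index=samples)
    return pd.DataFrame(columns).reindex(index=samples)


def genotypes_to_vcf(genotypes: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF export (GT only; locus ids as CHROM, SNP at POS 1)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.index)
            + "\n"
        )
        gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for locus in genotypes.columns:
            row = genotypes[locus]
            calls = [
                gt_code.get(v, "./.") if pd.notna(v) else "./." for v in row
            ]
            fh.write(f"{locus}\t1\t{locus}\tN\tN\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")
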