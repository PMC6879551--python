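"""Reference-guided RAD locus catalog and haplotype-presence calling."""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ..radproc.align import AlignmentRecord
from ..radproc.demux import ReadRecord
from .matrix import HaplotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class Locus:
    """One RAD locus with per-sample haplotype stacks.

    ``anchor`` is (scaffold, 1-based leftmost position, strand) for
    reference-guided loci; de novo loci carry a ``consensus`` sequence
    instead.  ``samples`` maps sample id -> list of (haplotype sequence,
    depth), all sequences equal length.
    """

    locus_id: str
    anchor: tuple[str, int, str] | None = None
    consensus: str | None = None
    samples: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def haplotype_seqs(self) -> list[str]:
        """All distinct haplotype sequences across samples, sorted."""
        return sorted({seq for haps in self.samples.values() for seq, _ in haps})


@dataclass
class LocusCatalog:
    loci: list[Locus] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loci)

    def by_id(self, locus_id: str) -> Locus:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for locus in self.loci:
            anchor = (
                f"{locus.anchor[0]}:{locus.anchor[1]}:{locus.anchor[2]}"
                if locus.anchor
                else ""
            )
            for sample, haps in locus.samples.items():
                for seq, depth in haps:
                    rows.append(
                        {"locus_id": locus.locus_id, "anchor": anchor,
                         "consensus": locus.consensus or "", "sample_id": sample,
                         "haplotype": seq, "depth": depth}
                    )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_reference_catalog(
    aligned_reads: Iterable[tuple[str, ReadRecord, AlignmentRecord]],
    min_stack_depth: int = 3,
) -> LocusCatalog:
    """Group aligned reads into loci keyed by (scaffold, position, strand).

    Within each sample, identical read sequences form stacks; stacks below
    ``min_stack_depth`` are discarded.  Surviving stacks are the sample's
    haplotypes at that locus.  Reads shorter than the locus's modal template
    length (truncated fragments) are dropped so all haplotypes at a locus
    have equal length.
    """
    grouped: dict[tuple[str, int, str], dict[str, Counter]] = defaultdict(
        lambda: defaultdict(Counter)
    )
    for sample_id, read, aln in aligned_reads:
        grouped[(aln.scaffold, aln.pos, aln.strand)][sample_id][read.sequence] += 1

    loci: list[Locus] = []
    for anchor in sorted(grouped):
        per_sample = grouped[anchor]
        lengths = Counter(
            len(seq) for counts in per_sample.values() for seq in counts
        )
        modal_len = lengths.most_common(1)[0][0]
        samples: dict[str, list[tuple[str, int]]] = {}
        for sample_id, counts in per_sample.items():
            haps = [
                (seq, depth)
                for seq, depth in sorted(counts.items())
                if depth >= min_stack_depth and len(seq) == modal_len
            ]
            if haps:
                samples[sample_id] = haps
        if samples:
            loci.append(
                Locus(
                    locus_id=f"{anchor[0]}:{anchor[1]}:{anchor[2]}",
                    anchor=anchor,
                    samples=samples,
                )
            )
    return LocusCatalog(loci=loci)


def call_symbiont_haplotypes(
    catalog: LocusCatalog,
    min_hap_depth: int = 6,
) -> HaplotypeMatrix:
    """Binary presence matrix over haplotypes with >= ``min_hap_depth`` coverage.

    A haplotype with depth exactly equal to the threshold is kept.  A sample
    x locus cell with no surviving haplotype is missing (NaN) at all of that
    locus's columns.  Haplotype columns that no sample supports at threshold
    are dropped entirely.
    """
    if not catalog.loci:
        warnings.warn("empty catalog: returning empty haplotype matrix")
        return HaplotypeMatrix(
            pd.DataFrame(columns=pd.MultiIndex.from_tuples([], names=["locus", "hap"]))
        )
    all_samples = sorted({s for locus in catalog.loci for s in locus.samples})
    columns: list[tuple[str, str]] = []
    hap_seqs: dict[tuple[str, str], str] = {}
    blocks: list[np.ndarray] = []
    for locus in catalog.loci:
        surviving: dict[str, list[str]] = {}
        for sample, haps in locus.samples.items():
            kept = [seq for seq, depth in haps if depth >= min_hap_depth]
            if kept:
                surviving[sample] = kept
        seqs = sorted({seq for kept in surviving.values() for seq in kept})
        if not seqs:
            continue
        hap_of = {seq: f"h{i}" for i, seq in enumerate(seqs)}
        block = np.full((len(all_samples), len(seqs)), np.nan)
        for si, sample in enumerate(all_samples):
            kept = surviving.get(sample)
            if kept is None:
                continue
            block[si] = 0.0
            for seq in kept:
                block[si, seqs.index(seq)] = 1.0
        for seq in seqs:
            columns.append((locus.locus_id, hap_of[seq]))
            hap_seqs[(locus.locus_id, hap_of[seq])] = seq
        blocks.append(block)
    if not blocks:
        warnings.warn("no haplotype reached the depth threshold")
        return HaplotypeMatrix(
            pd.DataFrame(index=all_samples,
                         columns=pd.MultiIndex.from_tuples([], names=["locus", "hap"]))
        )
    frame = pd.DataFrame(
        np.hstack(blocks),
        index=all_samples,
        columns=pd.MultiIndex.from_tuples(columns, names=["locus", "hap"]),
    )
    return HaplotypeMatrix(frame, hap_seqs=hap_seqs)
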