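"""Inline-barcode demultiplexing with single-mismatch rescue."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .._seq import hamming

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read, optionally after demultiplexing."""

    read_id: str
    sequence: str
    quality: str
    sample_id: str | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a Phred+33 FASTQ file as :class:`ReadRecord` objects."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            rid, _, comment = title.partition(" ")
            yield ReadRecord(read_id=rid, sequence=seq, quality=qual, comment=comment)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Load a sample sheet TSV (sample_id, barcode, location, year, length_mm)."""
    sheet = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    if "sample_id" in sheet.columns:
        sheet = sheet.set_index("sample_id")
    return sheet


def validate_barcodes(sheet: pd.DataFrame, max_mismatch: int = 1) -> None:
    barcodes = list(sheet["barcode"])
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("sample sheet contains duplicate barcodes")
    if any(len(b) != 10 for b in barcodes):
        raise ValueError("barcodes must be exactly 10 nt")
    if max_mismatch >= 1:
        min_required = 2 * max_mismatch + 1
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1 :]:
                if hamming(a, b) < min_required:
                    raise ValueError(
                        f"barcodes {a} and {b} are closer than {min_required} "
                        f"mismatches; unsafe for max_barcode_mismatch={max_mismatch}"
                    )


def demultiplex(
    reads: Iterable[ReadRecord],
    sheet: pd.DataFrame,
    max_barcode_mismatch: int = 1,
) -> tuple[dict[str, list[ReadRecord]], dict[str, int]]:
    """Assign reads to samples by their first 10 bases and strip the barcode.

    A read is assigned when its leading 10-mer is within
    ``max_barcode_mismatch`` of exactly one barcode; everything else goes to
    the ``"unassigned"`` bin (barcode retained).  Returns (bins, counts).
    """
    validate_barcodes(sheet, max_barcode_mismatch)
    by_barcode = {row.barcode: sid for sid, row in sheet.iterrows()}
    blen = 10
    bins: dict[str, list[ReadRecord]] = {sid: [] for sid in sheet.index}
    bins["unassigned"] = []
    counts = {sid: 0 for sid in sheet.index}
    counts["unassigned"] = 0

    for read in reads:
        prefix = read.sequence[:blen]
        sample = by_barcode.get(prefix)
        if sample is None and max_barcode_mismatch > 0 and len(prefix) == blen:
            hits = [
                sid for bc, sid in by_barcode.items()
                if hamming(prefix, bc) <= max_barcode_mismatch
            ]
            sample = hits[0] if len(hits) == 1 else None
        if sample is None:
            bins["unassigned"].append(read)
            counts["unassigned"] += 1
            continue
        bins[sample].append(
            replace(read, sequence=read.sequence[blen:], quality=read.quality[blen:],
                    sample_id=sample)
        )
        counts[sample] += 1

    logger.info("demultiplexed %d reads, %d unassigned",
                sum(counts.values()), counts["unassigned"])
    return bins, counts
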