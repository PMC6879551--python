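"""Three-way origin partitioning: symbiont / contaminant / host read bins."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .align import AlignmentRecord, SeedIndex, align_read
from .demux import ReadRecord

logger = logging.getLogger(__name__)


@dataclass
class PartitionResult:
    """Reads split exhaustively and disjointly into three origin bins.

    ``symbiont`` keeps the alignment record that earned the read its place;
    the bins together contain every input read exactly once.
    """

    symbiont: list[tuple[ReadRecord, AlignmentRecord]] = field(default_factory=list)
    contaminant: list[ReadRecord] = field(default_factory=list)
    host: list[ReadRecord] = field(default_factory=list)
    low_uniqueness_leaked: int = 0

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "symbiont": len(self.symbiont),
            "contaminant": len(self.contaminant),
            "host": len(self.host),
        }

    @property
    def total(self) -> int:
        return sum(self.sizes.values())


def partition_reads(
    reads: Iterable[ReadRecord],
    symbiont_ref: dict[str, str],
    decoy_refs: list[dict[str, str]] | None = None,
    min_uniqueness: int = 20,
    max_mismatches: int = 4,
    seed_length: int = 20,
    low_uniqueness_to_decoys: bool = True,
) -> PartitionResult:
    """Partition reads by alignment against the symbiont reference and decoys.

    A read lands in the symbiont bin iff it aligns to the symbiont reference
    with uniqueness strictly greater than ``min_uniqueness``.  Remaining
    reads aligning to any decoy genome are contaminants; everything else is
    host.  References may be passed as scaffold dicts or prebuilt
    :class:`SeedIndex` objects (cheaper when partitioning many samples).  Low-uniqueness symbiont hits are never sent to the symbiont bin;
    by default they are still screened against the decoys
    (``low_uniqueness_to_decoys=False`` sends them straight to the host bin).
    """
    sym_index = (
        symbiont_ref if isinstance(symbiont_ref, SeedIndex)
        else SeedIndex(symbiont_ref, k=seed_length)
    )
    decoy_indexes = [
        d if isinstance(d, SeedIndex) else SeedIndex(d, k=seed_length)
        for d in (decoy_refs or [])
    ]
    result = PartitionResult()
    for read in reads:
        aln = align_read(read, sym_index, max_mismatches)
        if aln is not None and aln.uniqueness > min_uniqueness:
            result.symbiont.append((read, aln))
            continue
        if aln is not None:
            result.low_uniqueness_leaked += 1
            if not low_uniqueness_to_decoys:
                result.host.append(read)
                continue
        hit_decoy = any(
            align_read(read, di, max_mismatches) is not None for di in decoy_indexes
        )
        if hit_decoy:
            result.contaminant.append(read)
        else:
            result.host.append(read)
    if result.low_uniqueness_leaked:
        logger.info(
            "%d reads aligned to the symbiont reference with low uniqueness "
            "and were excluded from the symbiont bin",
            result.low_uniqueness_leaked,
        )
    return result


def write_sam(
    alignments: Iterable[tuple[ReadRecord, AlignmentRecord]],
    reference: dict[str, str],
    path: str | Path,
) -> None:
    """Write minimal single-end SAM (ungapped, full-length match CIGAR)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for sid, seq in reference.items():
            fh.write(f"@SQ\tSN:{sid}\tLN:{len(seq)}\n")
        for read, aln in alignments:
            flag = 16 if aln.strand == "-" else 0
            fh.write(
                f"{read.read_id}\t{flag}\t{aln.scaffold}\t{aln.pos}\t"
                f"{aln.uniqueness}\t{len(read.sequence)}M\t*\t0\t0\t"
                f"{read.sequence}\t{read.quality}\n"
            )
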