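"""De novo locus assembly: exact stacks, within-sample merging, cross-sample catalog."""

from __future__ import annotations

from collections import Counter
from typing import Iterable

from .._seq import hamming
from ..radproc.demux import ReadRecord
from .catalog import Locus, LocusCatalog


def _sample_loci(
    reads: Iterable[ReadRecord],
    max_within_mismatch: int,
    min_stack_depth: int,
) -> list[tuple[str, list[tuple[str, int]]]]:
    """Within one sample: exact stacks merged greedily deepest-first.

    Returns a list of (founder consensus sequence, [(haplotype, depth), ...]).
    Stacks join the first (deepest) existing locus within
    ``max_within_mismatch``; ties in depth break by sequence order.
    """
    counts = Counter(r.sequence for r in reads)
    stacks = [
        (seq, depth) for seq, depth in counts.items() if depth >= min_stack_depth
    ]
    stacks.sort(key=lambda x: (-x[1], x[0]))
    loci: list[tuple[str, list[tuple[str, int]]]] = []
    for seq, depth in stacks:
        placed = False
        for i, (founder, members) in enumerate(loci):
            if len(founder) == len(seq) and hamming(founder, seq) <= max_within_mismatch:
                members.append((seq, depth))
                placed = True
                break
        if not placed:
            loci.append((seq, [(seq, depth)]))
    return loci


def build_denovo_catalog(
    reads_by_sample: dict[str, Iterable[ReadRecord]],
    max_within_mismatch: int = 2,
    max_catalog_mismatch: int = 1,
    min_stack_depth: int = 3,
) -> LocusCatalog:
    """Assemble loci without a reference.

    Per sample, exact-sequence stacks (depth >= ``min_stack_depth``) merge
    deepest-first into sample loci when within ``max_within_mismatch``.
    Sample-locus consensus sequences (the founder stack) then merge across
    samples into catalog loci when within ``max_catalog_mismatch`` of a
    catalog consensus, visited in lexicographic consensus order so ties are
    deterministic.
    """
    per_sample = {
        sid: _sample_loci(reads, max_within_mismatch, min_stack_depth)
        for sid, reads in reads_by_sample.items()
    }
    entries = sorted(
        (founder, sid, members)
        for sid, sl in per_sample.items()
        for founder, members in sl
    )
    catalog: list[Locus] = []
    for founder, sid, members in entries:
        target = None
        for locus in catalog:
            if len(locus.consensus) == len(founder) and (
                hamming(locus.consensus, founder) <= max_catalog_mismatch
            ):
                target = locus
                break
        if target is None:
            target = Locus(locus_id=f"dn{len(catalog):05d}", consensus=founder)
            catalog.append(target)
        target.samples.setdefault(sid, []).extend(members)
    return LocusCatalog(loci=catalog)
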