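"""K-mer-seeded ungapped read alignment with a simple uniqueness (MAPQ-like) score.

This is a behavioral stand-in for a short-read aligner: exact seed match on
either strand, ungapped extension counting mismatches, best placement
reported.  The only downstream contract is the uniqueness score's >20 cut
separating confident from ambiguous placements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .._seq import revcomp
from .demux import ReadRecord


@dataclass(frozen=True)
class AlignmentRecord:
    """An ungapped placement of a read on the forward reference strand."""

    read_id: str
    scaffold: str
    pos: int  # 1-based leftmost
    strand: str
    mismatches: int
    uniqueness: int  # 0-60, >20 means confidently unique


class SeedIndex:
    """Exact k-mer index of the forward strand of a reference."""

    def __init__(self, scaffolds: dict[str, str], k: int = 20):
        if not scaffolds or all(len(s) == 0 for s in scaffolds.values()):
            raise ValueError("reference is empty")
        self.k = k
        self.scaffolds = {sid: seq.upper() for sid, seq in scaffolds.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in self.scaffolds.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((sid, i))

    def candidates(self, oriented: str) -> set[tuple[str, int]]:
        """Candidate (scaffold, 0-based start) placements for an oriented read."""
        L, k = len(oriented), self.k
        if L < k:
            return set()
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        found: set[tuple[str, int]] = set()
        for o in offsets:
            for sid, i in self.index.get(oriented[o : o + k], ()):
                start = i - o
                if 0 <= start and start + L <= len(self.scaffolds[sid]):
                    found.add((sid, start))
        return found


def _count_mismatches(a: str, b: str, cap: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > cap:
                return n
    return n


def _uniqueness(margin: int) -> int:
    # tied best -> 3; margin 2+ -> 60; linear in between
    if margin <= 0:
        return 3
    if margin >= 2:
        return 60
    return int(3 + 28.5 * margin)


def align_read(
    read: ReadRecord | str,
    index: SeedIndex,
    max_mismatches: int = 4,
) -> AlignmentRecord | None:
    """Best ungapped placement of a read, or None if nothing has
    <= ``max_mismatches``.  Reverse-strand hits are reported at the leftmost
    forward-strand coordinate with strand '-'."""
    if isinstance(read, str):
        read = ReadRecord(read_id="anonymous", sequence=read, quality="I" * len(read))
    seq = read.sequence.upper()
    placements: list[tuple[int, str, int, str]] = []  # (mm, scaffold, pos0, strand)
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        for sid, start in index.candidates(oriented):
            ref_sub = index.scaffolds[sid][start : start + len(oriented)]
            mm = _count_mismatches(oriented, ref_sub, max_mismatches)
            if mm <= max_mismatches:
                placements.append((mm, sid, start, strand))
    if not placements:
        return None
    placements.sort(key=lambda p: (p[0], p[1], p[2], p[3]))
    best = placements[0]
    margin = placements[1][0] - best[0] if len(placements) > 1 else 2
    return AlignmentRecord(
        read_id=read.read_id,
        scaffold=best[1],
        pos=best[2] + 1,
        strand=best[3],
        mismatches=best[0],
        uniqueness=_uniqueness(margin),
    )


def align_reads(
    reads: Iterable[ReadRecord],
    reference: dict[str, str],
    max_mismatches: int = 4,
    seed_length: int = 20,
) -> dict[str, AlignmentRecord | None]:
    """Align many reads against a reference; returns read_id -> record (or None)."""
    index = SeedIndex(reference, k=seed_length)
    return {r.read_id: align_read(r, index, max_mismatches) for r in reads}
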