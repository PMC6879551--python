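"""In-silico double restriction digest and fragment size selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: default recognition sites and cut offsets (bases 5' of the cut, 0-based
#: offset into the site): G^AATTC and T^TAA.
ECORI_SITE = "GAATTC"
ECORI_CUT = 1
MSEI_SITE = "TTAA"
MSEI_CUT = 1


@dataclass(frozen=True)
class Fragment:
    """A retained double-digest fragment (1-based inclusive coordinates)."""

    scaffold: str
    start: int
    end: int
    ecori_end: str  # 'left' or 'right': which end carries the rare-cutter overhang

    def __len__(self) -> int:
        return self.end - self.start + 1


def _cut_positions(seq: str, site: str, offset: int) -> list[int]:
    """0-based positions at which the sequence is severed (overlap-aware)."""
    cuts = []
    i = seq.find(site)
    while i != -1:
        cuts.append(i + offset)
        i = seq.find(site, i + 1)
    return cuts


def digest_and_select(
    scaffolds: dict[str, str],
    enzyme_a: tuple[str, int] = (ECORI_SITE, ECORI_CUT),
    enzyme_b: tuple[str, int] = (MSEI_SITE, MSEI_CUT),
    size_window: tuple[int, int] = (150, 450),
) -> list[Fragment]:
    """Cut every scaffold at every forward-strand site of either enzyme and
    keep fragments with one end from each enzyme and a length inside the
    size window.

    Scaffold-terminal fragments have an un-cut end and are never retained.
    Returns fragments sorted by (scaffold order, start).
    """
    site_a, off_a = enzyme_a
    site_b, off_b = enzyme_b
    lo, hi = size_window
    fragments: list[Fragment] = []
    for sid, seq in scaffolds.items():
        seq = seq.upper()
        cuts = [(c, "A") for c in _cut_positions(seq, site_a, off_a)]
        cuts += [(c, "B") for c in _cut_positions(seq, site_b, off_b)]
        cuts.sort()
        for (c1, e1), (c2, e2) in zip(cuts, cuts[1:]):
            length = c2 - c1
            if {e1, e2} != {"A", "B"} or not lo <= length <= hi:
                continue
            fragments.append(
                Fragment(
                    scaffold=sid,
                    start=c1 + 1,
                    end=c2,
                    ecori_end="left" if e1 == "A" else "right",
                )
            )
    if not fragments:
        logger.warning("double digest retained no fragments in window %s", size_window)
    return fragments
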