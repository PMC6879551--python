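"""Sliding-window mean-quality read filter (process_radtags-style)."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .demux import ReadRecord

PHRED_OFFSET = 33


def _passes(qual: str, q_threshold: float, window_fraction: float) -> bool:
    scores = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - PHRED_OFFSET
    w = max(1, int(round(window_fraction * len(scores))))
    if len(scores) < w:
        return scores.mean() >= q_threshold
    cums = np.concatenate([[0.0], np.cumsum(scores)])
    means = (cums[w:] - cums[:-w]) / w
    return bool(means.min() >= q_threshold)


def quality_filter(
    reads: Iterable[ReadRecord],
    q_threshold: float = 20.0,
    window_fraction: float = 0.15,
) -> tuple[list[ReadRecord], dict]:
    """Drop reads whose sliding-window mean quality ever falls below threshold.

    Window length is ``window_fraction`` of the read length (15% default),
    advanced one base at a time.  ``q_threshold=0`` keeps everything.
    Returns (kept reads, report dict with input/kept/retained_fraction).
    """
    kept = []
    total = 0
    for read in reads:
        total += 1
        if q_threshold <= 0 or _passes(read.quality, q_threshold, window_fraction):
            kept.append(read)
    report = {
        "input": total,
        "kept": len(kept),
        "retained_fraction": (len(kept) / total) if total else 1.0,
    }
    return kept, report
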