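"""Per-sample QC on the symbiont bin: total reads and mean stack depth."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .align import AlignmentRecord
from .demux import ReadRecord


@dataclass(frozen=True)
class SampleQcReport:
    sample_id: str
    total_reads: int
    n_stacks: int
    mean_stack_depth: float
    passed: bool


def sample_qc(
    symbiont_bins: dict[str, list[tuple[ReadRecord, AlignmentRecord]]],
    min_reads: int = 100_000,
    min_mean_depth: float = 100.0,
) -> tuple[list[SampleQcReport], list[str]]:
    """Flag samples with too few reads or too shallow stacks.

    A stack is a group of identical read sequences at one (scaffold, pos,
    strand) placement; mean stack depth is reads / stacks.  A sample passes
    iff reads >= ``min_reads`` and mean depth >= ``min_mean_depth`` (a sample
    with ``min_reads - 1`` reads is discarded).  Raises if every sample
    fails.
    """
    reports: list[SampleQcReport] = []
    for sample, entries in symbiont_bins.items():
        stacks: dict[tuple, int] = {}
        for read, aln in entries:
            key = (aln.scaffold, aln.pos, aln.strand, read.sequence)
            stacks[key] = stacks.get(key, 0) + 1
        total = len(entries)
        mean_depth = (total / len(stacks)) if stacks else 0.0
        passed = total >= min_reads and mean_depth >= min_mean_depth
        reports.append(
            SampleQcReport(sample, total, len(stacks), mean_depth, passed)
        )
    passing = [r.sample_id for r in reports if r.passed]
    if reports and not passing:
        raise RuntimeError(
            "all samples failed QC "
            f"(min_reads={min_reads}, min_mean_depth={min_mean_depth}); "
            "nothing to analyze downstream"
        )
    return reports, passing


def qc_report_to_tsv(reports: list[SampleQcReport], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in reports]).to_csv(path, sep="\t", index=False)
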