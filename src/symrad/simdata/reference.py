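"""Toy annotated reference genomes: uniform sequence plus non-overlapping CDS."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .._seq import random_seq

_PRODUCTS = [
    "RNA chaperone",
    "two-component sensor histidine kinase",
    "methyl-accepting chemotaxis protein",
    "glycine dehydrogenase",
    "efflux transporter permease subunit",
    "serine protein kinase",
    "hypoxanthine phosphoribosyltransferase",
    "potassium uptake protein",
    "alpha/beta fold hydrolase",
    "ABC transporter substrate-binding protein",
    "unknown function",
]


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature on a reference scaffold (1-based, inclusive)."""

    scaffold: str
    start: int
    end: int
    strand: str
    gene: str
    product: str = "unknown function"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CDS {self.gene}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.gene}: strand must be + or -")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(f"CDS {self.gene}: length not divisible by 3")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, scaffold: str, pos: int) -> bool:
        return scaffold == self.scaffold and self.start <= pos <= self.end


@dataclass
class ReferenceGenome:
    """A multi-scaffold nucleotide reference with CDS annotations."""

    scaffolds: dict[str, str]
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sid, seq in self.scaffolds.items():
            if not seq:
                raise ValueError(f"scaffold {sid} is empty")
        for f in self.features:
            if f.scaffold not in self.scaffolds:
                raise ValueError(f"CDS {f.gene} on unknown scaffold {f.scaffold}")
            if f.end > len(self.scaffolds[f.scaffold]):
                raise ValueError(f"CDS {f.gene} extends past scaffold end")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def base(self, scaffold: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.scaffolds[scaffold][pos - 1]

    def features_on(self, scaffold: str) -> list[CdsFeature]:
        return [f for f in self.features if f.scaffold == scaffold]

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.scaffolds.items():
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for sid, seq in self.scaffolds.items():
                fh.write(f"##sequence-region {sid} 1 {len(seq)}\n")
            for i, f in enumerate(self.features):
                attrs = f"ID=cds{i};gene={f.gene};product={f.product}"
                fh.write(
                    f"{f.scaffold}\tsymrad\tCDS\t{f.start}\t{f.end}\t.\t"
                    f"{f.strand}\t0\t{attrs}\n"
                )

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path | None = None) -> "ReferenceGenome":
        from Bio import SeqIO

        scaffolds = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        features: list[CdsFeature] = []
        if gff3 is not None:
            with open(gff3) as fh:
                for line in fh:
                    if line.startswith("#") or not line.strip():
                        continue
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) < 9 or parts[2] != "CDS":
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    features.append(
                        CdsFeature(
                            scaffold=parts[0],
                            start=int(parts[3]),
                            end=int(parts[4]),
                            strand=parts[6],
                            gene=attrs.get("gene", attrs.get("ID", "unknown")),
                            product=attrs.get("product", "unknown function"),
                        )
                    )
        return cls(scaffolds=scaffolds, features=features)


def make_reference(
    n_scaffolds: int = 8,
    scaffold_lengths: int | list[int] = 25_000,
    cds_fraction: float = 0.6,
    seed: int = 0,
    name_prefix: str = "scaffold",
) -> ReferenceGenome:
    """Simulate an annotated toy reference genome.

    Sequence is i.i.d. uniform A/C/G/T.  Non-overlapping CDS features with
    lengths divisible by 3 are laid down left to right on alternating strands
    until ≈ ``cds_fraction`` of each scaffold is coding.  Deterministic for a
    given seed.

    Parameters
    ----------
    n_scaffolds:
        Number of scaffolds, numbered from 1.
    scaffold_lengths:
        One common length or a per-scaffold list; every length must be ≥ 1000.
    cds_fraction:
        Target coding fraction per scaffold, in [0, 0.95].
    """
    if isinstance(scaffold_lengths, int):
        lengths = [scaffold_lengths] * n_scaffolds
    else:
        lengths = list(scaffold_lengths)
        if len(lengths) != n_scaffolds:
            raise ValueError("scaffold_lengths must match n_scaffolds")
    if any(L < 1000 for L in lengths):
        raise ValueError("scaffold lengths must be >= 1000")
    if not 0.0 <= cds_fraction <= 0.95:
        raise ValueError("cds_fraction must be in [0, 0.95]")

    rng = np.random.default_rng(seed)
    scaffolds: dict[str, str] = {}
    features: list[CdsFeature] = []
    gene_serial = 0
    for i, L in enumerate(lengths):
        sid = f"{name_prefix}_{i + 1}"
        scaffolds[sid] = random_seq(L, rng)
        if cds_fraction == 0.0:
            continue
        # expected intergenic gap so coding/total ~= cds_fraction
        mean_gene = 750.0
        mean_gap = max(1.0, mean_gene * (1.0 - cds_fraction) / cds_fraction)
        pos = 1  # next free 1-based position
        strand_toggle = 0
        while True:
            gap = int(round(mean_gap * rng.uniform(0.5, 1.5)))
            start = pos + gap
            glen = 3 * int(rng.integers(100, 401))
            end = start + glen - 1
            if end > L:
                break
            gene_serial += 1
            features.append(
                CdsFeature(
                    scaffold=sid,
                    start=start,
                    end=end,
                    strand="+-"[strand_toggle],
                    gene=f"gene{gene_serial:04d}",
                    product=_PRODUCTS[gene_serial % len(_PRODUCTS)],
                )
            )
            strand_toggle ^= 1
            pos = end + 1
    return ReferenceGenome(scaffolds=scaffolds, features=features)
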