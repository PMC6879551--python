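"""Binary samples x (locus, haplotype) presence matrix with locus-level missingness."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class HaplotypeMatrix:
    """Presence (1.0) / absence (0.0) / missing (NaN) of haplotypes per sample.

    Columns are a two-level MultiIndex ``(locus, hap)``.  Missingness is a
    locus-level notion: if a sample has no surviving haplotype at a locus it
    is NaN at *all* of that locus's columns, never 0.
    """

    def __init__(self, data: pd.DataFrame, hap_seqs: dict[tuple[str, str], str] | None = None):
        if not isinstance(data.columns, pd.MultiIndex) or data.columns.nlevels != 2:
            raise ValueError("columns must be a (locus, hap) MultiIndex")
        self.data = data.astype(float)
        self.hap_seqs = hap_seqs or {}
        self.validate()

    # ------------------------------------------------------------ accessors

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def validate(self) -> None:
        """Enforce the all-or-none missingness invariant per locus."""
        isna = self.data.isna()
        per_locus_any = isna.T.groupby(level=0).any().T
        per_locus_all = isna.T.groupby(level=0).all().T
        if not per_locus_any.equals(per_locus_all):
            raise ValueError("missingness must be locus-level (all columns NaN or none)")

    def locus_observed(self) -> pd.DataFrame:
        """Boolean samples x loci frame: locus has a call in that sample."""
        observed = self.data.notna().T.groupby(level=0).any().T
        return observed.loc[:, self.loci]

    def present_counts(self) -> pd.DataFrame:
        """Samples x loci count of present haplotypes (NaN where locus missing)."""
        counts = self.data.T.groupby(level=0).sum(min_count=1).T
        return counts.loc[:, self.loci]

    # ---------------------------------------------------------- subsetting

    def subset_samples(self, samples) -> "HaplotypeMatrix":
        sub = self.data.loc[list(samples)]
        return HaplotypeMatrix(sub, hap_seqs=self.hap_seqs)

    def subset_loci(self, loci) -> "HaplotypeMatrix":
        keep = set(loci)
        cols = [c for c in self.data.columns if c[0] in keep]
        seqs = {c: s for c, s in self.hap_seqs.items() if c[0] in keep}
        return HaplotypeMatrix(self.data.loc[:, cols], hap_seqs=seqs)

    # ----------------------------------------------------------------- I/O

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.columns = [f"{l}|{h}" for l, h in out.columns]
        out.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
        frame.columns = pd.MultiIndex.from_tuples(
            [tuple(c.rsplit("|", 1)) for c in frame.columns], names=["locus", "hap"]
        )
        return cls(frame)

    def __repr__(self) -> str:
        return (
            f"<HaplotypeMatrix {len(self.samples)} samples x {self.n_loci} loci "
            f"({self.data.shape[1]} haplotype columns)>"
        )
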