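"""Simulator ground truth: compositions, planted variants, truth haplotypes.

The truth-side variant-effect classifier below deliberately relies on
Biopython's translation machinery; the analysis-side classifier in
:mod:`symrad.capdiv.annotate` is an independent implementation, so the two
can be cross-validated without sharing code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .digest import Fragment
from .reads import locus_template
from .reference import CdsFeature, ReferenceGenome
from .strains import Variant


@dataclass
class TruthSet:
    """Everything the simulator knows that the pipeline must rediscover."""

    compositions: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    populations: dict[str, str] = field(default_factory=dict)
    strain_variants: dict[str, list[Variant]] = field(default_factory=dict)
    variant_effects: dict[Variant, tuple[str, str]] = field(default_factory=dict)
    host_genotypes: pd.DataFrame | None = None
    sample_lengths: dict[str, float] = field(default_factory=dict)

    def strain_count(self, sample: str) -> int:
        return len(self.compositions[sample])

    def to_tsvs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        rows = [
            {"sample_id": s, "strain_id": strain, "abundance": ab,
             "population": self.populations.get(s, "")}
            for s, comp in self.compositions.items()
            for strain, ab in comp
        ]
        pd.DataFrame(rows).to_csv(outdir / "truth_compositions.tsv", sep="\t", index=False)
        vrows = [
            {"strain_id": s, "scaffold": v.scaffold, "pos": v.pos,
             "ref": v.ref, "alt": v.alt,
             "variant_type": self.variant_effects.get(v, ("", ""))[0],
             "variant_effect": self.variant_effects.get(v, ("", ""))[1]}
            for s, vs in self.strain_variants.items()
            for v in vs
        ]
        pd.DataFrame(vrows).to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
        if self.host_genotypes is not None:
            self.host_genotypes.to_csv(outdir / "truth_host_genotypes.tsv", sep="\t")


def _codon_at(ref: ReferenceGenome, feat: CdsFeature, pos: int,
              override: str | None = None) -> str:
    """Coding-strand codon containing genome position ``pos`` of ``feat``."""
    seq = ref.scaffolds[feat.scaffold]
    if override is not None:
        seq = seq[: pos - 1] + override + seq[pos:]
    if feat.strand == "+":
        i = (pos - feat.start) // 3
        codon = seq[feat.start - 1 + 3 * i : feat.start + 2 + 3 * i]
    else:
        i = (feat.end - pos) // 3
        codon = str(Seq(seq[feat.end - 3 * i - 3 : feat.end - 3 * i]).reverse_complement())
    return codon


def classify_truth_effect(
    ref: ReferenceGenome, v: Variant, upstream_window: int = 500
) -> tuple[str, str]:
    """(variant type, effect) of a planted substitution, via Biopython translation.

    Types: synonymous/LOW, non-synonymous/MODERATE, stop-gained/HIGH inside a
    CDS; upstream/MODIFIER within ``upstream_window`` bp 5' of a CDS start;
    otherwise intergenic/none.
    """
    for feat in ref.features_on(v.scaffold):
        if feat.contains(v.scaffold, v.pos):
            old = str(Seq(_codon_at(ref, feat, v.pos)).translate())
            new = str(Seq(_codon_at(ref, feat, v.pos, override=v.alt)).translate())
            if new == "*" and old != "*":
                return "stop-gained", "HIGH"
            if new == old:
                return "synonymous", "LOW"
            return "non-synonymous", "MODERATE"
    for feat in ref.features_on(v.scaffold):
        if feat.strand == "+" and feat.start - upstream_window <= v.pos < feat.start:
            return "upstream", "MODIFIER"
        if feat.strand == "-" and feat.end < v.pos <= feat.end + upstream_window:
            return "upstream", "MODIFIER"
    return "intergenic", "none"


def annotate_truth_variants(ref: ReferenceGenome, truth: TruthSet,
                            upstream_window: int = 500) -> None:
    """Fill ``truth.variant_effects`` for every planted variant."""
    for variants in truth.strain_variants.values():
        for v in variants:
            if v not in truth.variant_effects:
                truth.variant_effects[v] = classify_truth_effect(ref, v, upstream_window)


@dataclass
class TruthHaplotypes:
    """Truth-side haplotype structure at the simulated RAD loci."""

    #: locus id -> strain id -> template sequence
    by_locus: dict[str, dict[str, str]]
    #: locus id -> (scaffold, anchor position, strand)
    anchors: dict[str, tuple[str, int, str]]

    def sample_haplotypes(self, composition: list[tuple[str, float]]) -> dict[str, set[str]]:
        """Distinct haplotype sequences each locus shows for one light organ."""
        strains = [s for s, _ in composition]
        return {
            locus: {haps[s] for s in strains if s in haps}
            for locus, haps in self.by_locus.items()
        }

    def distinguishing_loci(self, composition: list[tuple[str, float]]) -> int:
        """Max number of member strains any single locus can tell apart."""
        per_locus = self.sample_haplotypes(composition)
        return max((len(h) for h in per_locus.values()), default=0)


def truth_haplotypes(
    ref: ReferenceGenome,
    fragments: list[Fragment],
    strain_variants: dict[str, list[Variant]],
    template_len: int = 90,
) -> TruthHaplotypes:
    """Per-locus, per-strain template sequences implied by planted variants."""
    by_locus: dict[str, dict[str, str]] = {}
    anchors: dict[str, tuple[str, int, str]] = {}
    for frag in fragments:
        _, (sc, pos, strand) = locus_template(ref.scaffolds, frag, [], template_len)
        locus_id = f"{sc}:{pos}:{strand}"
        table = {}
        for strain, variants in strain_variants.items():
            tpl, _ = locus_template(ref.scaffolds, frag, variants, template_len)
            table[strain] = tpl
        by_locus[locus_id] = table
        anchors[locus_id] = (sc, pos, strand)
    return TruthHaplotypes(by_locus=by_locus, anchors=anchors)


def truth_haplotype_matrix(
    truth_haps: TruthHaplotypes,
    compositions: dict[str, list[tuple[str, float]]],
):
    """Samples x (locus, haplotype) presence matrix straight from the truth.

    No missing data: every locus is observed in every sample.  Returns a
    :class:`symrad.loci.HaplotypeMatrix`.
    """
    from ..loci.matrix import HaplotypeMatrix

    samples = list(compositions)
    columns: list[tuple[str, str]] = []
    hap_seqs: dict[tuple[str, str], str] = {}
    hap_ids: dict[str, dict[str, str]] = {}  # locus -> seq -> hap id
    for locus, table in truth_haps.by_locus.items():
        seqs = sorted(set(table.values()))
        ids = {}
        for i, s in enumerate(seqs):
            hap = f"h{i}"
            ids[s] = hap
            columns.append((locus, hap))
            hap_seqs[(locus, hap)] = s
        hap_ids[locus] = ids

    data = np.zeros((len(samples), len(columns)))
    col_index = {c: j for j, c in enumerate(columns)}
    for i, sample in enumerate(samples):
        strains = [s for s, _ in compositions[sample]]
        for locus, table in truth_haps.by_locus.items():
            for strain in strains:
                seq = table.get(strain)
                if seq is not None:
                    data[i, col_index[(locus, hap_ids[locus][seq])]] = 1.0
    frame = pd.DataFrame(
        data, index=samples, columns=pd.MultiIndex.from_tuples(columns, names=["locus", "hap"])
    )
    return HaplotypeMatrix(frame, hap_seqs=hap_seqs)
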