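"""Simplified variant-type / functional-effect annotation of outlier haplotypes.

Substitutions are classified against the annotated reference: inside a CDS
the affected codon is translated strand-aware (synonymous / non-synonymous /
stop-gained); within a configurable window 5' of a CDS start and outside any
CDS the variant is "upstream"; a haplotype identical to the reference is
"consensus".  Effects follow the fixed mapping synonymous->LOW,
non-synonymous->MODERATE, stop-gained->HIGH, upstream->MODIFIER.

The genetic code here is hand-rolled on purpose so this classifier stays
independent of the simulator's truth annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .._seq import revcomp
from ..simdata.reference import CdsFeature, ReferenceGenome

EFFECT_BY_TYPE = {
    "synonymous": "LOW",
    "non-synonymous": "MODERATE",
    "stop-gained": "HIGH",
    "upstream": "MODIFIER",
    "consensus": "none",
    "intergenic": "none",
}

#: most to least severe
SEVERITY_ORDER = ["HIGH", "MODERATE", "LOW", "MODIFIER", "none"]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class VariantCall:
    """A substitution observed in a haplotype, in forward-reference coordinates."""

    scaffold: str
    pos: int
    ref: str
    alt: str
    variant_type: str = "intergenic"
    effect: str = "none"
    gene: str = ""
    product: str = ""


@dataclass
class HaplotypeAnnotation:
    """All variant calls for one haplotype plus a most-severe summary."""

    variants: list[VariantCall] = field(default_factory=list)
    summary_type: str = "consensus"
    summary_effect: str = "none"
    gene: str = ""
    product: str = ""
    multi_cds: bool = False


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper()]


def _codon_with(seq: str, feat: CdsFeature, pos: int, base: str) -> tuple[str, str]:
    """(reference codon, mutated codon) on the coding strand for ``pos``."""
    mutated = seq[: pos - 1] + base + seq[pos:]
    if feat.strand == "+":
        i = (pos - feat.start) // 3
        lo = feat.start - 1 + 3 * i
        return seq[lo : lo + 3], mutated[lo : lo + 3]
    i = (feat.end - pos) // 3
    hi = feat.end - 3 * i
    return revcomp(seq[hi - 3 : hi]), revcomp(mutated[hi - 3 : hi])


def classify_variant(
    scaffold: str,
    pos: int,
    alt: str,
    ref: ReferenceGenome,
    upstream_window: int = 500,
) -> list[VariantCall]:
    """Classify one substitution; one call per overlapping CDS (flagged rare case)."""
    refbase = ref.base(scaffold, pos)
    containing = [f for f in ref.features_on(scaffold) if f.contains(scaffold, pos)]
    calls: list[VariantCall] = []
    seq = ref.scaffolds[scaffold]
    for feat in containing:
        old_codon, new_codon = _codon_with(seq, feat, pos, alt)
        old_aa, new_aa = translate_codon(old_codon), translate_codon(new_codon)
        if new_aa == "*" and old_aa != "*":
            vtype = "stop-gained"
        elif new_aa == old_aa:
            vtype = "synonymous"
        else:
            vtype = "non-synonymous"
        calls.append(
            VariantCall(scaffold, pos, refbase, alt, vtype, EFFECT_BY_TYPE[vtype],
                        gene=feat.gene, product=feat.product)
        )
    if calls:
        return calls
    for feat in ref.features_on(scaffold):
        in_window = (
            feat.strand == "+" and feat.start - upstream_window <= pos < feat.start
        ) or (feat.strand == "-" and feat.end < pos <= feat.end + upstream_window)
        if in_window:
            return [
                VariantCall(scaffold, pos, refbase, alt, "upstream", "MODIFIER",
                            gene=feat.gene, product=feat.product)
            ]
    return [VariantCall(scaffold, pos, refbase, alt, "intergenic", "none")]


def variants_from_haplotype(
    haplotype: str,
    anchor: tuple[str, int, str],
    ref: ReferenceGenome,
) -> list[tuple[int, str]]:
    """Mismatching forward-strand (position, observed base) pairs for a haplotype.

    ``anchor`` is the (scaffold, leftmost forward position, strand) of the
    locus; '-' strand haplotypes are reverse-complemented before comparison.
    """
    scaffold, start, strand = anchor
    oriented = haplotype if strand == "+" else revcomp(haplotype)
    ref_sub = ref.scaffolds[scaffold][start - 1 : start - 1 + len(oriented)]
    if len(ref_sub) != len(oriented):
        raise ValueError("haplotype extends past the scaffold end")
    return [
        (start + i, obs)
        for i, (obs, expected) in enumerate(zip(oriented, ref_sub))
        if obs != expected
    ]


def annotate_haplotype(
    haplotype: str,
    anchor: tuple[str, int, str],
    ref: ReferenceGenome,
    upstream_window: int = 500,
) -> HaplotypeAnnotation:
    """Full annotation of one haplotype: per-variant calls + most-severe summary."""
    mismatches = variants_from_haplotype(haplotype, anchor, ref)
    ann = HaplotypeAnnotation()
    if not mismatches:
        # gene context of a consensus haplotype, if any CDS overlaps the locus
        scaffold, start, _ = anchor
        for feat in ref.features_on(scaffold):
            if feat.start <= start + len(haplotype) - 1 and feat.end >= start:
                ann.gene, ann.product = feat.gene, feat.product
                break
        return ann
    calls: list[VariantCall] = []
    genes = set()
    for pos, obs in mismatches:
        vc = classify_variant(anchor[0], pos, obs, ref, upstream_window)
        calls.extend(vc)
        genes.update(c.gene for c in vc if c.gene)
    ann.variants = calls
    ann.multi_cds = any(
        sum(c.pos == pos for c in calls) > 1 for pos, _ in mismatches
    )
    severity = {e: i for i, e in enumerate(SEVERITY_ORDER)}
    worst = min(calls, key=lambda c: severity[c.effect])
    ann.summary_type = worst.variant_type
    ann.summary_effect = worst.effect
    ann.gene = worst.gene or (sorted(genes)[0] if genes else "")
    ann.product = worst.product
    return ann
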