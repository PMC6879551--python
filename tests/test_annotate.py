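import pytest

from symrad._seq import revcomp
from symrad.capdiv import (
    EFFECT_BY_TYPE,
    SEVERITY_ORDER,
    annotate_haplotype,
    classify_variant,
    variants_from_haplotype,
)
from symrad.simdata import make_reference
from symrad.simdata.reference import CdsFeature, ReferenceGenome
from symrad.simdata.truth import classify_truth_effect
from symrad.simdata.strains import Variant


def _ref_with_cds(seq, start, end, strand="+", gene="g1", product="prod"):
    return ReferenceGenome(
        scaffolds={"sc": seq},
        features=[CdsFeature("sc", start, end, strand, gene, product)],
    )


def test_effect_mapping_table():
    assert EFFECT_BY_TYPE["synonymous"] == "LOW"
    assert EFFECT_BY_TYPE["non-synonymous"] == "MODERATE"
    assert EFFECT_BY_TYPE["stop-gained"] == "HIGH"
    assert EFFECT_BY_TYPE["upstream"] == "MODIFIER"
    assert SEVERITY_ORDER.index("HIGH") < SEVERITY_ORDER.index("MODERATE")
    assert SEVERITY_ORDER.index("MODERATE") < SEVERITY_ORDER.index("LOW")
    assert SEVERITY_ORDER.index("LOW") < SEVERITY_ORDER.index("MODIFIER")


def test_synonymous_gaa_to_gag():
    # GAA -> GAG is Glu -> Glu on the + strand
    seq = "A" * 9 + "GAA" + "T" * 9  # CDS covers the GAA codon
    ref = _ref_with_cds(seq, 10, 12)
    call = classify_variant("sc", 12, "G", ref)[0]
    assert call.variant_type == "synonymous"
    assert call.effect == "LOW"


def test_stop_gained_tgg_to_tga():
    seq = "A" * 9 + "TGG" + "T" * 9
    ref = _ref_with_cds(seq, 10, 12)
    call = classify_variant("sc", 12, "A", ref)[0]
    assert call.variant_type == "stop-gained"
    assert call.effect == "HIGH"


def test_non_synonymous():
    seq = "A" * 9 + "AAA" + "T" * 9  # Lys
    ref = _ref_with_cds(seq, 10, 12)
    call = classify_variant("sc", 10, "G", ref)[0]  # GAA = Glu
    assert call.variant_type == "non-synonymous"
    assert call.effect == "MODERATE"


def test_minus_strand_codon():
    # coding strand is revcomp; put TGG (Trp) on the minus strand:
    # genome shows CCA at positions 10-12 -> coding reads TGG
    seq = "A" * 9 + "CCA" + "T" * 9
    ref = _ref_with_cds(seq, 10, 12, strand="-")
    # genome T at pos 10 -> coding A at third codon position: TGG -> TGA stop
    call = classify_variant("sc", 10, "T", ref)[0]
    assert call.variant_type == "stop-gained"


def test_upstream_window_strand_aware():
    seq = "A" * 2000
    plus = _ref_with_cds(seq, 1000, 1299, strand="+")
    assert classify_variant("sc", 700, "C", plus)[0].variant_type == "upstream"
    assert classify_variant("sc", 499, "C", plus)[0].variant_type == "intergenic"
    minus = _ref_with_cds(seq, 1000, 1299, strand="-")
    assert classify_variant("sc", 1500, "C", minus)[0].variant_type == "upstream"
    assert classify_variant("sc", 700, "C", minus)[0].variant_type == "intergenic"


def test_consensus_haplotype():
    seq = "ACGT" * 50
    ref = _ref_with_cds(seq, 1, 30)
    ann = annotate_haplotype(seq[10:60], ("sc", 11, "+"), ref)
    assert ann.summary_type == "consensus"
    assert ann.summary_effect == "none"
    assert ann.variants == []


def test_variants_from_minus_strand_haplotype():
    seq = "ACGTACGTACGTACGTACGT"
    ref = ReferenceGenome(scaffolds={"sc": seq})
    hap = revcomp(seq[4:14])
    hap = hap[:3] + ("A" if hap[3] != "A" else "C") + hap[4:]
    calls = variants_from_haplotype(hap, ("sc", 5, "-"), ref)
    assert len(calls) == 1
    pos, obs = calls[0]
    # position maps back to the forward strand
    assert 5 <= pos <= 14
    assert obs != seq[pos - 1]


def test_most_severe_summary():
    # two variants in one haplotype: one synonymous, one stop-gained
    seq = "A" * 9 + "GAATGG" + "T" * 9
    ref = _ref_with_cds(seq, 10, 15)
    hap = list(seq[9:15])
    hap[2] = "G"  # GAA -> GAG synonymous
    hap[5] = "A"  # TGG -> TGA stop
    ann = annotate_haplotype("".join(hap), ("sc", 10, "+"), ref)
    assert len(ann.variants) == 2
    assert ann.summary_type == "stop-gained"
    assert ann.summary_effect == "HIGH"


def test_agreement_with_truth_classifier(sim_clean):
    # independent implementations agree on every planted variant
    ref = sim_clean.reference
    mismatches = []
    for strain, variants in sim_clean.truth.strain_variants.items():
        for v in variants:
            expected = sim_clean.truth.variant_effects[v]
            calls = classify_variant(v.scaffold, v.pos, v.alt, ref)
            got = (calls[0].variant_type, calls[0].effect)
            got = (got[0], got[1] if got[1] != "none" else "none")
            if (got[0], {"LOW": "LOW", "MODERATE": "MODERATE", "HIGH": "HIGH",
                         "MODIFIER": "MODIFIER", "none": "none"}[got[1]]) != expected:
                mismatches.append((v, expected, got))
    assert mismatches == []


def test_annotation_roundtrip_on_haplotypes(sim_clean):
    # every planted coding variant recovered from the truth haplotypes with
    # exactly the truth's (type, effect); no false stop-gained calls
    ref = sim_clean.reference
    truth = sim_clean.truth
    for locus, table in sim_clean.truth_haps.by_locus.items():
        anchor = sim_clean.truth_haps.anchors[locus]
        for strain, hap in table.items():
            ann = annotate_haplotype(hap, anchor, ref)
            planted = {
                (v.scaffold, v.pos): truth.variant_effects[v]
                for v in truth.strain_variants[strain]
            }
            for call in ann.variants:
                expected = planted.get((call.scaffold, call.pos))
                assert expected is not None, "variant not in truth"
                assert (call.variant_type, call.effect) == expected
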