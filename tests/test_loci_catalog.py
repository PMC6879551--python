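import numpy as np
import pytest

from conftest import as_read_records, truth_tag
from symrad.loci import build_reference_catalog, call_symbiont_haplotypes
from symrad.radproc import SeedIndex, demultiplex, partition_reads, quality_filter
from symrad.radproc.align import AlignmentRecord
from symrad.radproc.demux import ReadRecord


def _aligned(sample, seq, n, anchor=("sc", 100, "+")):
    out = []
    for i in range(n):
        read = ReadRecord(f"{sample}_{seq[:3]}_{i}", seq, "I" * len(seq))
        aln = AlignmentRecord(read.read_id, anchor[0], anchor[1], anchor[2], 0, 60)
        out.append((sample, read, aln))
    return out


def test_single_stack_called():
    cat = build_reference_catalog(_aligned("s1", "AAA", 5), min_stack_depth=3)
    assert len(cat) == 1
    assert cat.loci[0].samples["s1"] == [("AAA", 5)]


def test_shallow_stack_dropped():
    entries = _aligned("s1", "AAA", 5) + _aligned("s1", "AAT", 2)
    cat = build_reference_catalog(entries, min_stack_depth=3)
    assert cat.loci[0].samples["s1"] == [("AAA", 5)]


def test_brute_force_grouping_oracle(sim_clean):
    # on <= 200 reads, locus grouping equals brute-force grouping by key
    reads = as_read_records(sim_clean.all_reads)
    bins, _ = demultiplex(reads, sim_clean.sample_sheet)
    sample = sim_clean.sample_sheet.index[0]
    part = partition_reads(bins[sample][:200], sim_clean.reference.scaffolds)
    entries = [(sample, r, a) for r, a in part.symbiont]
    cat = build_reference_catalog(entries, min_stack_depth=1)

    oracle = {}
    for _, r, a in entries:
        oracle.setdefault((a.scaffold, a.pos, a.strand), []).append(r.sequence)
    oracle_keys = {k for k, seqs in oracle.items()}
    assert {l.anchor for l in cat.loci} == oracle_keys
    for locus in cat.loci:
        seqs = sorted(oracle[locus.anchor])
        called = sorted(
            s for s, d in locus.samples[sample] for _ in range(d)
        )
        assert called == seqs


def test_haplotypes_match_truth_strains(sim_clean):
    # error-free: every called haplotype is a truth strain template
    reads = as_read_records(sim_clean.all_reads)
    bins, _ = demultiplex(reads, sim_clean.sample_sheet)
    sym_index = SeedIndex(sim_clean.reference.scaffolds)
    entries = []
    for sample in sim_clean.sample_sheet.index[:4]:
        kept, _ = quality_filter(bins[sample])
        part = partition_reads(kept, sym_index)
        entries.extend((sample, r, a) for r, a in part.symbiont)
    cat = build_reference_catalog(entries, min_stack_depth=3)
    assert len(cat) > 0
    truth = sim_clean.truth_haps
    for locus in cat.loci:
        locus_truth = truth.by_locus.get(locus.locus_id)
        assert locus_truth is not None, f"unexpected locus {locus.locus_id}"
        valid = set(locus_truth.values())
        for sample, haps in locus.samples.items():
            for seq, depth in haps:
                assert seq in valid


def test_haplotype_fidelity_set_equality(sim_clean):
    # with generous depth, per-sample haplotype sets equal truth alleles present
    reads = as_read_records(sim_clean.all_reads)
    bins, _ = demultiplex(reads, sim_clean.sample_sheet)
    sym_index = SeedIndex(sim_clean.reference.scaffolds)
    sample = sim_clean.sample_sheet.index[0]
    part = partition_reads(bins[sample], sym_index)
    cat = build_reference_catalog([(sample, r, a) for r, a in part.symbiont],
                                  min_stack_depth=1)
    comp = sim_clean.truth.compositions[sample]
    expected = sim_clean.truth_haps.sample_haplotypes(comp)
    matched = checked = 0
    for locus in cat.loci:
        called = {seq for seq, _ in locus.samples.get(sample, [])}
        if not called:
            continue
        checked += 1
        matched += called == expected[locus.locus_id]
    assert checked > 0
    # depth is stochastic; rare alleles may miss reads entirely, so demand most
    assert matched / checked >= 0.8


def test_matrix_monotone_in_depth_threshold(sim_clean):
    reads = as_read_records(sim_clean.all_reads)
    bins, _ = demultiplex(reads, sim_clean.sample_sheet)
    sym_index = SeedIndex(sim_clean.reference.scaffolds)
    entries = []
    for sample in sim_clean.sample_sheet.index[:6]:
        part = partition_reads(bins[sample], sym_index)
        entries.extend((sample, r, a) for r, a in part.symbiont)
    cat = build_reference_catalog(entries)
    present = []
    for depth in (5, 6, 8, 10):
        hm = call_symbiont_haplotypes(cat, min_hap_depth=depth)
        present.append(np.nansum(hm.data.to_numpy()) if hm.data.size else 0.0)
    assert all(a >= b for a, b in zip(present, present[1:]))


def test_depth_boundary_exactly_six():
    entries = _aligned("s1", "AAA", 6) + _aligned("s2", "AAA", 5)
    cat = build_reference_catalog(entries, min_stack_depth=3)
    hm = call_symbiont_haplotypes(cat, min_hap_depth=6)
    col = ("sc:100:+", "h0")
    assert hm.data.loc["s1", col] == 1.0
    assert np.isnan(hm.data.loc["s2", col])  # below threshold -> locus missing


def test_column_dropped_when_no_sample_reaches_threshold():
    entries = _aligned("s1", "AAA", 6)
    cat = build_reference_catalog(entries)
    hm = call_symbiont_haplotypes(cat, min_hap_depth=10)
    assert hm.data.shape[1] == 0


def test_empty_catalog_warns():
    from symrad.loci.catalog import LocusCatalog

    with pytest.warns(UserWarning):
        hm = call_symbiont_haplotypes(LocusCatalog())
    assert hm.data.empty
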