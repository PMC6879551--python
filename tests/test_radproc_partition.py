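import numpy as np
import pytest

from conftest import as_read_records, truth_tag
from symrad._seq import random_seq
from symrad.radproc import (
    SeedIndex,
    demultiplex,
    partition_reads,
    sample_qc,
    write_sam,
)
from symrad.radproc.demux import ReadRecord


def test_no_symbiont_alignment_all_host():
    rng = np.random.default_rng(0)
    ref = {"s": random_seq(2000, rng)}
    reads = [ReadRecord(f"r{i}", random_seq(90, rng), "I" * 90) for i in range(20)]
    part = partition_reads(reads, ref)
    assert part.sizes == {"symbiont": 0, "contaminant": 0, "host": 20}


def test_partition_exhaustive_disjoint(sim_small):
    reads = as_read_records(sim_small.all_reads)
    bins, _ = demultiplex(reads, sim_small.sample_sheet)
    sample = sim_small.sample_sheet.index[0]
    part = partition_reads(bins[sample], sim_small.reference.scaffolds)
    assert part.total == len(bins[sample])
    ids = (
        [r.read_id for r, _ in part.symbiont]
        + [r.read_id for r in part.contaminant]
        + [r.read_id for r in part.host]
    )
    assert len(ids) == len(set(ids))


def test_truth_bin_accuracy(sim_small):
    # >= 98% of truth-symbiont reads in symbiont bin and vice versa (error 0.001)
    reads = as_read_records(sim_small.all_reads)
    bins, _ = demultiplex(reads, sim_small.sample_sheet)
    sym_index = SeedIndex(sim_small.reference.scaffolds)
    sym_ok = sym_total = host_ok = host_total = 0
    for sample in sim_small.sample_sheet.index[:6]:
        part = partition_reads(bins[sample], sym_index)
        in_sym = {r.read_id for r, _ in part.symbiont}
        in_host = {r.read_id for r in part.host}
        for read in bins[sample]:
            strain = truth_tag(read)[1]
            is_host = ".a" in strain or ".b" in strain
            if is_host:
                host_total += 1
                host_ok += read.read_id in in_host
            else:
                sym_total += 1
                sym_ok += read.read_id in in_sym
    assert sym_total and host_total
    assert sym_ok / sym_total >= 0.98
    assert host_ok / host_total >= 0.98


def test_multimapper_excluded_from_symbiont_bin():
    rng = np.random.default_rng(1)
    core = random_seq(200, rng)
    ref = {
        "a": random_seq(300, rng) + core + random_seq(300, rng),
        "b": random_seq(300, rng) + core + random_seq(300, rng),
    }
    read = ReadRecord("dup", core[40:130], "I" * 90)
    part = partition_reads([read], ref)
    assert part.sizes["symbiont"] == 0
    assert part.sizes["host"] == 1  # no decoys: falls through to host
    assert part.low_uniqueness_leaked == 1


def test_decoy_catches_contaminant():
    rng = np.random.default_rng(2)
    sym = {"s": random_seq(2000, rng)}
    decoy = {"d": random_seq(2000, rng)}
    read = ReadRecord("c1", decoy["d"][100:190], "I" * 90)
    part = partition_reads([read], sym, decoy_refs=[decoy])
    assert part.sizes["contaminant"] == 1


def test_partition_idempotent_on_symbiont_bin(sim_small):
    reads = as_read_records(sim_small.all_reads)
    bins, _ = demultiplex(reads, sim_small.sample_sheet)
    sample = sim_small.sample_sheet.index[1]
    part1 = partition_reads(bins[sample], sim_small.reference.scaffolds)
    part2 = partition_reads([r for r, _ in part1.symbiont], sim_small.reference.scaffolds)
    assert {r.read_id for r, _ in part2.symbiont} == {r.read_id for r, _ in part1.symbiont}


def test_sample_qc_thresholds():
    rng = np.random.default_rng(3)
    ref = {"s": random_seq(1000, rng)}
    index = SeedIndex(ref)
    template = ref["s"][100:190]

    def mk_bin(n):
        from symrad.radproc import align_read

        reads = [ReadRecord(f"r{i}", template, "I" * 90) for i in range(n)]
        return [(r, align_read(r, index)) for r in reads]

    bins = {"good": mk_bin(50), "bad": mk_bin(5)}
    reports, passing = sample_qc(bins, min_reads=10, min_mean_depth=10)
    assert passing == ["good"]
    by_id = {r.sample_id: r for r in reports}
    assert by_id["good"].mean_stack_depth == 50.0  # one stack of 50
    assert not by_id["bad"].passed

    # boundary: one read below the threshold is discarded
    reports, passing = sample_qc({"x": mk_bin(9), "y": mk_bin(10)}, min_reads=10, min_mean_depth=0)
    assert passing == ["y"]

    # (0, 0) thresholds: identity
    reports, passing = sample_qc(bins, min_reads=0, min_mean_depth=0)
    assert set(passing) == {"good", "bad"}

    with pytest.raises(RuntimeError):
        sample_qc({"bad": mk_bin(2)}, min_reads=1000, min_mean_depth=1000)


def test_sam_output_parses_with_pysam(tmp_path, sim_small):
    pysam = pytest.importorskip("pysam")
    reads = as_read_records(sim_small.all_reads)
    bins, _ = demultiplex(reads, sim_small.sample_sheet)
    sample = sim_small.sample_sheet.index[0]
    part = partition_reads(bins[sample], sim_small.reference.scaffolds)
    path = tmp_path / "out.sam"
    write_sam(part.symbiont, sim_small.reference.scaffolds, path)
    with pysam.AlignmentFile(str(path), "r") as sam:
        n = 0
        for rec in sam:
            n += 1
            assert rec.cigarstring.endswith("M")
            assert rec.mapping_quality >= 0
        assert n == len(part.symbiont)
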