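# symrad

Dual-genome ddRAD-seq toolkit for jointly genotyping an animal host and its
intracellular/light-organ bacterial symbiont from the same multiplexed
single-end libraries, and for contrasting their population structure.

The package covers the full path from raw (simulated) reads to inference:

| stage | module | what it does |
| --- | --- | --- |
| simulate | `symrad.simdata` | toy annotated reference genomes, hierarchically structured symbiont strain pools, a panmictic diploid host, in-silico EcoRI+MseI double digest, truth-tagged 100 bp barcoded FASTQ reads |
| process | `symrad.radproc` | inline-barcode demultiplexing (1-mismatch rescue), sliding-window quality filter, k-mer-seeded ungapped alignment with a uniqueness (MAPQ-like) score, symbiont/contaminant/host partitioning, per-sample QC |
| call | `symrad.loci` | reference-guided locus catalog (min stack depth 3), haplotype presence/absence matrix (≥6x haplotype depth), de novo host catalog, first-SNP-per-locus diploid genotypes (MAF ≥5%), the 70%/50%/15% missing-data filter cascade with per-year dataset splits |
| infer | `symrad.popstats` | Bray-Curtis and missing-aware Euclidean distances, PCoA, one-way and pairwise PERMANOVA, Mantel tests, Weir–Cockerham F_ST, within-light-organ strain-count estimator, strain-count-vs-length regression — all with explicit permutation engines and exhaustive-enumeration modes |
| diverge | `symrad.capdiv` | constrained analysis of principal coordinates (db-RDA), extreme-CAP-score outlier haplotype selection, simplified variant-type/effect annotation (synonymous→LOW, non-synonymous→MODERATE, stop-gained→HIGH, upstream→MODIFIER), locus genome map |

Every simulator output carries ground truth (strain compositions, population
labels, planted variants with coding effects), so each downstream stage is
testable without external data.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which runs the heavier
statistical calibrations (type-I error over 500 replicate simulations, power
and host/symbiont-contrast checks over dozens of replicates); the whole run
takes a few minutes on one core.

## CLI

```bash
# simulate a dataset (flat key=value config, see symrad.simdata.SimConfig)
symrad simulate --config sim.cfg --out simdir --seed 1

# demultiplex + quality filter + partition + QC
symrad partition --reads simdir/reads.fastq --sheet simdir/sample_sheet.tsv \
    --ref simdir/reference.fasta --out partdir

# distance-based structure statistics on a haplotype matrix TSV
symrad structure --matrix matrix.tsv --meta meta.tsv --dataset 2014 \
    --factor location --stat permanova --perms 999 --seed 1 --out permanova.tsv

# constrained ordination and outlier haplotypes
symrad cap --matrix matrix.tsv --meta meta.tsv --factor location \
    --pct 0.99 --gap 2.0 --out outliers.tsv
```

## Notes on scope

- Alignment is ungapped by design (the simulator plants substitutions only);
  no indels, PCR duplicates, adapter read-through or paired-end support.
- The variant-effect classifier covers the four effect categories above plus
  consensus/intergenic — not a full effect-prediction ontology.
- PCoA reports negative eigenvalues unmodified (no Lingoes/Cailliez
  correction).
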