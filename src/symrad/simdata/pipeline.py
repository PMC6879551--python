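"""End-to-end simulation driver: genomes -> pools -> organs -> multiplexed FASTQ."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .._seq import hamming, random_seq
from .digest import digest_and_select
from .host import simulate_host  # noqa: F401  (re-exported convenience)
from .organs import compose_all_organs
from .reads import SimulatedRead, generate_reads, host_haplotype_pairs, write_fastq
from .reference import ReferenceGenome, make_reference
from .strains import simulate_strain_pools
from .truth import (
    TruthHaplotypes,
    TruthSet,
    annotate_truth_variants,
    truth_haplotypes,
)


@dataclass
class SimConfig:
    """Flat parameter set for :func:`simulate_dataset` (all keys overridable
    from a ``key=value`` config file via :meth:`from_file`)."""

    # symbiont reference
    n_scaffolds: int = 8
    scaffold_length: int = 25_000
    cds_fraction: float = 0.6
    # host reference
    host_n_scaffolds: int = 4
    host_scaffold_length: int = 25_000
    host_n_sites: int = 200
    host_maf: float = 0.3
    # strain pools
    n_groups: int = 2
    pools_per_group: int = 2
    strains_per_pool: int = 12
    theta_w: float = 0.001
    theta_b: float = 0.002
    # sampling design
    samples_per_site: int = 20
    year: int = 2014
    mixed: bool = False
    # light organs
    k_min: int = 2
    k_max: int = 10
    # sequencing
    depth_mean: float = 60.0
    host_depth_mean: float = 30.0
    dispersion: float = 5.0
    error_rate: float = 0.001
    read_len: int = 100
    size_min: int = 150
    size_max: int = 450
    include_host_reads: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Parse a flat ``key=value`` file (one pair per line, # comments)."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "bool": lambda s: s.lower() in {"1", "true", "yes"}}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in types:
                    raise KeyError(f"unknown simulation parameter {key!r}")
                kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)


def make_barcodes(n: int, rng: np.random.Generator, length: int = 10, min_dist: int = 3) -> list[str]:
    """Greedy set of ``n`` barcodes, pairwise Hamming distance >= ``min_dist``."""
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        cand = random_seq(length, rng)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not generate enough well-separated barcodes")
        if all(hamming(cand, b) >= min_dist for b in barcodes):
            barcodes.append(cand)
    return barcodes


@dataclass
class SymbiontContext:
    """A fixed digested reference reused across replicate simulations."""

    reference: ReferenceGenome
    fragments: list


def make_symbiont_context(
    n_scaffolds: int = 8,
    scaffold_length: int = 25_000,
    cds_fraction: float = 0.6,
    seed: int = 0,
    size_window: tuple[int, int] = (150, 450),
) -> SymbiontContext:
    ref = make_reference(n_scaffolds, scaffold_length, cds_fraction, seed=seed)
    return SymbiontContext(ref, digest_and_select(ref.scaffolds, size_window=size_window))


def simulate_symbiont_matrix(
    ctx: SymbiontContext,
    n_groups: int = 2,
    pools_per_group: int = 2,
    samples_per_site: int = 20,
    strains_per_pool: int = 12,
    theta_w: float = 0.001,
    theta_b: float = 0.002,
    k_range=range(2, 11),
    mixed: bool = False,
    seed: int = 0,
    template_len: int = 90,
):
    """Truth-level replicate: pools -> organs -> haplotype presence matrix.

    Skips read generation entirely (every locus observed in every sample),
    which is what the replicate-heavy statistical calibrations need.
    Returns (HaplotypeMatrix, site labels Series, TruthHaplotypes,
    compositions dict).
    """
    rng = np.random.default_rng(seed)
    pools = simulate_strain_pools(
        ctx.reference, n_groups, pools_per_group, strains_per_pool,
        theta_w, theta_b, seed=int(rng.integers(2**31)),
    )
    sample_sites = {}
    for pool in pools:
        for i in range(samples_per_site):
            sample_sites[f"{pool.pool_id}_{i:02d}"] = pool.pool_id
    compositions = compose_all_organs(
        sample_sites, pools, k_range=k_range, mixed=mixed,
        seed=int(rng.integers(2**31)),
    )
    strain_variants = {s: v for p in pools for s, v in p.strains.items()}
    t_haps = truth_haplotypes(ctx.reference, ctx.fragments, strain_variants,
                              template_len=template_len)
    from .truth import truth_haplotype_matrix

    matrix = truth_haplotype_matrix(t_haps, compositions)
    labels = pd.Series(sample_sites, name="location").loc[matrix.samples]
    return matrix, labels, t_haps, compositions


@dataclass
class SimResult:
    """In-memory handle on everything one simulation produced."""

    config: SimConfig
    reference: ReferenceGenome
    host_reference: ReferenceGenome
    pools: list
    fragments: list
    host_fragments: list
    sample_sheet: pd.DataFrame
    truth: TruthSet
    truth_haps: TruthHaplotypes
    reads_by_sample: dict[str, list[SimulatedRead]] = field(default_factory=dict)

    @property
    def all_reads(self) -> list[SimulatedRead]:
        return [r for reads in self.reads_by_sample.values() for r in reads]


def simulate_dataset(
    config: SimConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    generate_fastq: bool = True,
) -> SimResult:
    """Run the full simulation and optionally write all artefacts to disk.

    Outputs (when ``out_dir`` is given): ``reference.fasta``/``.gff3``,
    ``host_reference.fasta``, ``sample_sheet.tsv``, ``reads.fastq`` (one
    multiplexed library) and the truth TSVs.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)

    ref = make_reference(cfg.n_scaffolds, cfg.scaffold_length, cfg.cds_fraction,
                         seed=int(rng.integers(2**31)))
    host_ref = make_reference(cfg.host_n_scaffolds, cfg.host_scaffold_length, 0.0,
                              seed=int(rng.integers(2**31)), name_prefix="host_scaffold")
    window = (cfg.size_min, cfg.size_max)
    fragments = digest_and_select(ref.scaffolds, size_window=window)
    host_fragments = digest_and_select(host_ref.scaffolds, size_window=window)

    pools = simulate_strain_pools(
        ref, cfg.n_groups, cfg.pools_per_group, cfg.strains_per_pool,
        cfg.theta_w, cfg.theta_b, seed=int(rng.integers(2**31)),
    )

    # sample sheet
    site_ids = [p.pool_id for p in pools]
    samples = []
    for site in site_ids:
        for i in range(cfg.samples_per_site):
            samples.append((f"{site}_{i:02d}", site))
    barcodes = make_barcodes(len(samples), rng)
    sheet = pd.DataFrame(
        {
            "sample_id": [s for s, _ in samples],
            "barcode": barcodes,
            "location": [site for _, site in samples],
            "year": cfg.year,
            "length_mm": np.round(rng.uniform(20.0, 45.0, size=len(samples)), 1),
        }
    ).set_index("sample_id")

    truth = TruthSet()
    truth.populations = dict(zip(sheet.index, sheet["location"]))
    truth.sample_lengths = dict(zip(sheet.index, sheet["length_mm"]))
    for pool in pools:
        truth.strain_variants.update(pool.strains)

    truth.compositions = compose_all_organs(
        dict(zip(sheet.index, sheet["location"])), pools,
        k_range=range(cfg.k_min, cfg.k_max + 1), mixed=cfg.mixed,
        seed=int(rng.integers(2**31)),
    )
    annotate_truth_variants(ref, truth)
    t_haps = truth_haplotypes(ref, fragments, truth.strain_variants,
                              template_len=cfg.read_len - 10)

    # host diploid haplotypes for read-level simulation
    host_comps, host_hap_variants, host_sites = host_haplotype_pairs(
        host_ref.scaffolds, cfg.host_n_sites, len(sheet),
        sample_ids=list(sheet.index), maf=cfg.host_maf,
        seed=int(rng.integers(2**31)),
    )
    site_cols = [f"{v.scaffold}:{v.pos}" for v in host_sites]
    geno = pd.DataFrame(0.0, index=list(sheet.index), columns=site_cols)
    for sid in sheet.index:
        for hap in ("a", "b"):
            carried = {(v.scaffold, v.pos) for v in host_hap_variants[f"{sid}.{hap}"]}
            for v in host_sites:
                if (v.scaffold, v.pos) in carried:
                    geno.loc[sid, f"{v.scaffold}:{v.pos}"] += 1.0
    truth.host_genotypes = geno

    reads_by_sample: dict[str, list[SimulatedRead]] = {}
    if generate_fastq:
        for sid in sheet.index:
            barcode = sheet.loc[sid, "barcode"]
            sym = generate_reads(
                fragments, truth.compositions[sid], ref.scaffolds,
                truth.strain_variants, barcode, sid,
                depth_mean=cfg.depth_mean, dispersion=cfg.dispersion,
                error_rate=cfg.error_rate, read_len=cfg.read_len,
                rng=rng,
            )
            reads = sym
            if cfg.include_host_reads:
                host = generate_reads(
                    host_fragments, host_comps[sid], host_ref.scaffolds,
                    host_hap_variants, barcode, sid,
                    depth_mean=cfg.host_depth_mean, dispersion=cfg.dispersion,
                    error_rate=cfg.error_rate, read_len=cfg.read_len,
                    rng=rng, id_prefix="simh",
                )
                reads = sym + host
            reads_by_sample[sid] = reads

    result = SimResult(
        config=cfg, reference=ref, host_reference=host_ref, pools=pools,
        fragments=fragments, host_fragments=host_fragments,
        sample_sheet=sheet, truth=truth, truth_haps=t_haps,
        reads_by_sample=reads_by_sample,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ref.to_fasta(out / "reference.fasta")
        ref.to_gff3(out / "reference.gff3")
        host_ref.to_fasta(out / "host_reference.fasta")
        sheet.to_csv(out / "sample_sheet.tsv", sep="\t")
        truth.to_tsvs(out)
        if generate_fastq:
            write_fastq(result.all_reads, out / "reads.fastq")
    return result
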