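"""FASTQ read generation from digested fragments and strain haplotypes.

Reads start at the rare-cutter (EcoRI) end of each retained fragment, carry a
10 bp inline barcode, and encode their origin in the FASTQ comment field as
``truth:<sample>|<strain>|<scaffold>:<anchor>:<strand>[|trunc]`` so that any
standard parser ignores it but tests can audit assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._seq import BASES, revcomp
from .digest import Fragment
from .strains import Variant

DEFAULT_QUAL_CHAR = "F"  # Phred+33 Q37


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str
    comment: str

    def fastq(self) -> str:
        return f"@{self.read_id} {self.comment}\n{self.sequence}\n+\n{self.quality}\n"


def apply_variants(seq: str, start: int, variants: list[Variant], scaffold: str) -> str:
    """Apply substitutions (1-based genome coords) to ``seq`` beginning at ``start``."""
    if not variants:
        return seq
    out = list(seq)
    end = start + len(seq) - 1
    for v in variants:
        if v.scaffold == scaffold and start <= v.pos <= end:
            out[v.pos - start] = v.alt
    return "".join(out)


def locus_template(
    scaffolds: dict[str, str],
    frag: Fragment,
    variants: list[Variant] | None = None,
    template_len: int = 90,
) -> tuple[str, tuple[str, int, str]]:
    """The sequenced template at a fragment's EcoRI end, variants applied.

    Returns ``(template, (scaffold, forward-strand leftmost position, strand))``.
    Templates from right-end EcoRI fragments are reverse-complemented so the
    read always begins at the cut site; the anchor is always the leftmost
    position of the template on the forward reference strand (matching how an
    aligner reports the placement).  Fragments shorter than ``template_len``
    yield truncated templates.
    """
    seq = scaffolds[frag.scaffold]
    variants = variants or []
    if frag.ecori_end == "left":
        t_start = frag.start
        t_end = min(frag.end, frag.start + template_len - 1)
        sub = seq[t_start - 1 : t_end]
        sub = apply_variants(sub, t_start, variants, frag.scaffold)
        return sub, (frag.scaffold, t_start, "+")
    t_end = frag.end
    t_start = max(frag.start, frag.end - template_len + 1)
    sub = seq[t_start - 1 : t_end]
    sub = apply_variants(sub, t_start, variants, frag.scaffold)
    return revcomp(sub), (frag.scaffold, t_start, "-")


def _seq_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0:
        return seq
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < error_rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        alts = [b for b in BASES if b != out[i]]
        out[i] = alts[rng.integers(0, 3)]
    return "".join(out)


def generate_reads(
    fragments: list[Fragment],
    composition: list[tuple[str, float]],
    scaffolds: dict[str, str],
    strain_variants: dict[str, list[Variant]],
    barcode: str,
    sample_id: str,
    depth_mean: float = 20.0,
    dispersion: float = 5.0,
    error_rate: float = 0.0,
    read_len: int = 100,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    id_prefix: str = "sim",
) -> list[SimulatedRead]:
    """Emit barcoded single-end reads for one sample.

    Per fragment and strain the read count is negative binomial with mean
    ``depth_mean * abundance`` and dispersion ``dispersion`` (variance
    mean + mean^2/dispersion).  Substitution errors hit template and barcode
    cycles uniformly at ``error_rate``.
    """
    if not 0.0 <= error_rate <= 0.02:
        raise ValueError("error_rate must be in [0, 0.02]")
    if len(barcode) != 10:
        raise ValueError("barcode must be exactly 10 nt")
    if rng is None:
        rng = np.random.default_rng(seed)
    template_len = read_len - len(barcode)
    reads: list[SimulatedRead] = []
    serial = 0
    for frag in fragments:
        for strain, abundance in composition:
            mean = depth_mean * abundance
            if mean <= 0:
                continue
            p = dispersion / (dispersion + mean)
            depth = int(rng.negative_binomial(dispersion, p))
            if depth == 0:
                continue
            template, (sc, anchor, strand) = locus_template(
                scaffolds, frag, strain_variants.get(strain, []), template_len
            )
            trunc = "|trunc" if len(template) < template_len else ""
            tag = f"truth:{sample_id}|{strain}|{sc}:{anchor}:{strand}{trunc}"
            for _ in range(depth):
                serial += 1
                seq = _seq_errors(barcode + template, error_rate, rng)
                reads.append(
                    SimulatedRead(
                        read_id=f"{id_prefix}_{sample_id}_{serial:06d}",
                        sequence=seq,
                        quality=DEFAULT_QUAL_CHAR * len(seq),
                        comment=tag,
                    )
                )
    return reads


def write_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.fastq())


def host_haplotype_pairs(
    host_ref_scaffolds: dict[str, str],
    n_sites: int,
    n_samples: int,
    sample_ids: list[str] | None = None,
    maf: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, list[tuple[str, float]]], dict[str, list[Variant]], list[Variant]]:
    """Plant biallelic sites in a host reference and phase diploid samples.

    Every sample gets two equally abundant haplotypes ("<sample>.a"/".b"),
    each carrying the alt allele at a planted site with probability ``maf``.
    Returns (per-sample composition, per-haplotype variant lists, site list).
    """
    rng = np.random.default_rng(seed)
    ids = list(host_ref_scaffolds)
    lengths = np.array([len(host_ref_scaffolds[s]) for s in ids])
    cuts = np.concatenate([[0], np.cumsum(lengths)])
    L = int(cuts[-1])
    sites_idx = np.sort(rng.choice(L, size=min(n_sites, L), replace=False))
    sites: list[Variant] = []
    for g in sites_idx:
        i = int(np.searchsorted(cuts, g, side="right") - 1)
        pos = int(g - cuts[i]) + 1
        refbase = host_ref_scaffolds[ids[i]][pos - 1]
        alts = [b for b in BASES if b != refbase]
        sites.append(Variant(ids[i], pos, refbase, alts[rng.integers(0, 3)]))

    if sample_ids is None:
        sample_ids = [f"h{i:03d}" for i in range(n_samples)]
    compositions: dict[str, list[tuple[str, float]]] = {}
    hap_variants: dict[str, list[Variant]] = {}
    for sid in sample_ids:
        for hap in ("a", "b"):
            carried = [v for v in sites if rng.random() < maf]
            hap_variants[f"{sid}.{hap}"] = carried
        compositions[sid] = [(f"{sid}.a", 0.5), (f"{sid}.b", 0.5)]
    return compositions, hap_variants, sites
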