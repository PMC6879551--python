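"""Hierarchically structured symbiont strain pools expressed as variant sets.

Strains are haploid genomes represented as substitution lists against the
reference.  Structure has two levels: island *groups* share group-level
variants (per-site density ``theta_b``), and each strain carries private
variants (density ``theta_w``).  Site pools within a group therefore differ
only through their strains' private variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .._seq import mutate_base
from .reference import ReferenceGenome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution against the reference (1-based)."""

    scaffold: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide variants are supported")


@dataclass
class StrainPool:
    """Strains available at one site, keyed by strain id."""

    pool_id: str
    group_id: str
    strains: dict[str, list[Variant]] = field(default_factory=dict)
    theta_w: float = 0.0
    theta_b: float = 0.0

    @property
    def strain_ids(self) -> list[str]:
        return list(self.strains)


def _site_index(ref: ReferenceGenome) -> tuple[list[str], np.ndarray]:
    ids = list(ref.scaffolds)
    lengths = np.array([len(ref.scaffolds[s]) for s in ids])
    return ids, np.concatenate([[0], np.cumsum(lengths)])


def _draw_variants(
    ref: ReferenceGenome, density: float, rng: np.random.Generator
) -> list[Variant]:
    """Poisson(density * genome length) substitutions at distinct sites."""
    ids, cuts = _site_index(ref)
    L = int(cuts[-1])
    n = int(rng.poisson(density * L))
    n = min(n, L)
    sites = rng.choice(L, size=n, replace=False) if n else np.array([], dtype=int)
    out = []
    for g in np.sort(sites):
        i = int(np.searchsorted(cuts, g, side="right") - 1)
        pos = int(g - cuts[i]) + 1
        refbase = ref.base(ids[i], pos)
        out.append(Variant(ids[i], pos, refbase, mutate_base(refbase, rng)))
    return out


def _merge(first: list[Variant], second: list[Variant]) -> list[Variant]:
    """Union of variant lists; position collisions resolved by keeping `first`."""
    seen = {(v.scaffold, v.pos) for v in first}
    merged = list(first)
    for v in second:
        if (v.scaffold, v.pos) in seen:
            logger.debug("variant collision at %s:%d, keeping first", v.scaffold, v.pos)
            continue
        merged.append(v)
    return merged


def simulate_strain_pools(
    ref: ReferenceGenome,
    n_groups: int = 2,
    pools_per_group: int = 2,
    strains_per_pool: int = 12,
    theta_w: float = 0.001,
    theta_b: float = 0.002,
    seed: int = 0,
    pool_ids: list[str] | None = None,
) -> list[StrainPool]:
    """Simulate site-specific strain pools under a two-level hierarchy.

    Each group draws a set of group-level variants shared by every strain of
    every pool in the group; each strain then adds private variants.  Pool
    ids default to ``g<i>p<j>`` but can be supplied (row-major across groups).
    """
    for rate, name in ((theta_w, "theta_w"), (theta_b, "theta_b")):
        if not 0.0 <= rate <= 0.02:
            raise ValueError(f"{name} must be in [0, 0.02]")
    rng = np.random.default_rng(seed)
    if pool_ids is not None and len(pool_ids) != n_groups * pools_per_group:
        raise ValueError("pool_ids length must equal n_groups * pools_per_group")

    pools: list[StrainPool] = []
    k = 0
    for gi in range(n_groups):
        group_id = f"group{gi}"
        group_variants = _draw_variants(ref, theta_b, rng)
        for pi in range(pools_per_group):
            pid = pool_ids[k] if pool_ids is not None else f"g{gi}p{pi}"
            k += 1
            pool = StrainPool(pool_id=pid, group_id=group_id,
                              theta_w=theta_w, theta_b=theta_b)
            for si in range(strains_per_pool):
                private = _draw_variants(ref, theta_w, rng)
                pool.strains[f"{pid}_s{si}"] = _merge(group_variants, private)
            pools.append(pool)
    return pools
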