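"""Weir & Cockerham (1984) F_ST from diploid 0/1/2 genotype matrices."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class FstResult:
    pop1: str
    pop2: str
    theta: float
    p: float
    p_adjusted: float
    n_permutations: int


def _components(G: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) for r populations.

    ``G`` is samples x loci with values 0/1/2 or NaN; loci where fewer than
    two populations have data, or with no allele-frequency variation left
    defined, yield NaN components and are excluded by the caller.
    """
    pops = pd.unique(labels)
    r = len(pops)
    n_i = np.stack([(~np.isnan(G[labels == p])).sum(axis=0) for p in pops])  # r x L
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nanmean(G[labels == p], axis=0) / 2.0 for p in pops])
        h_i = np.stack(
            [
                np.nansum((G[labels == p] == 1.0), axis=0)
                / np.maximum((~np.isnan(G[labels == p])).sum(axis=0), 1)
                for p in pops
            ]
        )
        n_bar = n_i.sum(axis=0) / r
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1.0)) * (
                p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0
            )
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0

    # undefined where a population has no data or n_bar <= 1
    bad = (n_i == 0).any(axis=0) | (n_bar <= 1.0)
    # monomorphic loci carry no information
    mono = (p_bar <= 0.0) | (p_bar >= 1.0)
    for arr in (a, b, c):
        arr[bad | mono] = np.nan
    return a, b, c


def wc_theta(genotypes: pd.DataFrame | np.ndarray, labels) -> float:
    """Multi-locus Weir–Cockerham theta: sum(a) / sum(a+b+c) over usable loci."""
    G = genotypes.to_numpy(dtype=float) if isinstance(genotypes, pd.DataFrame) else np.asarray(genotypes, dtype=float)
    labels = np.asarray(list(labels))
    a, b, c = _components(G, labels)
    denom = a + b + c
    usable = ~np.isnan(denom) & (denom != 0.0)
    if not usable.any():
        return float("nan")
    return float(np.nansum(a[usable]) / np.nansum(denom[usable]))


def weir_cockerham_fst(
    genotypes: pd.DataFrame,
    populations,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> list[FstResult]:
    """Pairwise multi-locus theta with permutation p-values, Bonferroni-adjusted.

    ``populations`` maps sample id -> label.  For each population pair the
    null permutes individuals between the two groups; p uses the
    (1 + exceedances)/(1 + N) estimator; adjusted p = min(1, p * n_pairs).
    """
    populations = pd.Series(dict(populations)) if not isinstance(populations, pd.Series) else populations
    populations = populations.loc[genotypes.index]
    pops = list(pd.unique(populations))
    pairs = list(combinations(pops, 2))
    rng = np.random.default_rng(seed)
    results = []
    for p1, p2 in pairs:
        mask = populations.isin([p1, p2])
        G = genotypes.loc[mask].to_numpy(dtype=float)
        labels = populations[mask].to_numpy()
        theta = wc_theta(G, labels)
        exceed = 0
        for _ in range(n_permutations):
            perm_labels = labels[rng.permutation(len(labels))]
            t_perm = wc_theta(G, perm_labels)
            if not np.isnan(t_perm) and t_perm >= theta - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
        results.append(FstResult(p1, p2, theta, p, 1.0, n_permutations))
    m = len(results)
    for r in results:
        r.p_adjusted = min(1.0, r.p * m)
    return results
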