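"""Diploid host genotype simulator with an optional Balding–Nichols structure dial."""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd


def simulate_host(
    pop_sizes: dict[str, int] | int,
    n_loci: int = 1000,
    fst_target: float = 0.0,
    maf_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate diploid 0/1/2 genotypes at biallelic loci.

    Ancestral minor-allele frequencies are drawn from ``maf_dist`` (default
    Uniform(0.05, 0.5)).  With ``fst_target == 0`` all samples draw genotypes
    from the ancestral frequencies (panmixia).  With ``fst_target > 0`` each
    population's frequency is a Balding–Nichols beta perturbation
    ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` so the realized multi-locus F_ST is
    approximately the target.

    Returns (genotypes DataFrame samples x loci, truth dict with ancestral
    frequencies, per-population frequencies and population labels).
    """
    if isinstance(pop_sizes, int):
        pop_sizes = {"pop1": pop_sizes}
    if n_loci < 100:
        raise ValueError("n_loci must be >= 100")
    if not 0.0 <= fst_target < 0.5:
        raise ValueError("fst_target must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    if maf_dist is None:
        p_anc = rng.uniform(0.05, 0.5, size=n_loci)
    else:
        p_anc = np.asarray(maf_dist(rng, n_loci), dtype=float)
        if p_anc.shape != (n_loci,) or np.any((p_anc <= 0) | (p_anc >= 1)):
            raise ValueError("maf_dist must return n_loci frequencies in (0,1)")

    pop_freqs: dict[str, np.ndarray] = {}
    blocks = []
    labels = []
    sample_ids = []
    for pop, n in pop_sizes.items():
        if fst_target > 0.0:
            F = fst_target
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            p_pop = rng.beta(a, b)
        else:
            p_pop = p_anc.copy()
        pop_freqs[pop] = p_pop
        blocks.append(rng.binomial(2, p_pop, size=(n, n_loci)))
        labels.extend([pop] * n)
        sample_ids.extend(f"{pop}_h{i:03d}" for i in range(n))

    genotypes = pd.DataFrame(
        np.vstack(blocks),
        index=sample_ids,
        columns=[f"hl{j:05d}" for j in range(n_loci)],
        dtype=float,
    )
    truth = {
        "ancestral_freq": p_anc,
        "population_freq": pop_freqs,
        "populations": pd.Series(labels, index=sample_ids, name="population"),
        "fst_target": fst_target,
    }
    return genotypes, truth
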