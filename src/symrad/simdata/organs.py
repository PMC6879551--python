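"""Light-organ strain compositions: how many strains, and in what proportions."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .strains import StrainPool


def compose_light_organ(
    available_strains: Sequence[str],
    k_range: Iterable[int] = range(2, 11),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[tuple[str, float]]:
    """Draw one light organ's strain composition.

    The strain count ``k`` is uniform on ``k_range``; member strains are
    drawn without replacement from ``available_strains``; relative abundances
    are symmetric Dirichlet(1) and sum to one.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    k_values = sorted(set(int(k) for k in k_range))
    if not k_values or k_values[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    if k_values[-1] > len(available_strains):
        raise ValueError(
            f"k_range asks for up to {k_values[-1]} strains but only "
            f"{len(available_strains)} are available"
        )
    k = int(rng.choice(k_values))
    members = [available_strains[i] for i in rng.choice(len(available_strains), size=k, replace=False)]
    abundances = rng.dirichlet(np.ones(k))
    return list(zip(members, abundances.tolist()))


def compose_all_organs(
    sample_sites: dict[str, str],
    pools: list[StrainPool],
    k_range: Iterable[int] = range(2, 11),
    mixed: bool = False,
    seed: int = 0,
) -> dict[str, list[tuple[str, float]]]:
    """Compose every sample's light organ.

    ``sample_sites`` maps sample id -> site (pool) id.  By default each
    sample draws from its own site's pool.  With ``mixed=True`` every sample
    draws from the union of all pools' strains — the exchangeable,
    no-structure regime used for null calibration.
    """
    rng = np.random.default_rng(seed)
    by_pool = {p.pool_id: p.strain_ids for p in pools}
    union = [s for p in pools for s in p.strain_ids]
    compositions: dict[str, list[tuple[str, float]]] = {}
    for sample, site in sample_sites.items():
        strains = union if mixed else by_pool[site]
        compositions[sample] = compose_light_organ(strains, k_range=k_range, rng=rng)
    return compositions
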