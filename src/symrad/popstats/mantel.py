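"""Mantel test: correlation of two distance matrices over the same samples."""

from __future__ import annotations

from itertools import permutations as iter_permutations

import numpy as np

from .distance import DistanceMatrix


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("constant distance vector: Mantel r undefined")
    return float((xc * yc).sum() / denom)


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_permutations: int | str = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pearson correlation of lower-triangle distances, one-sided permutation p.

    Both matrices must share the same sample ids in the same order.  The
    permutation null permutes rows and columns of ``D2`` simultaneously;
    ``p = (1 + #{r_perm >= r_obs}) / (1 + N)``, or the exact enumeration over
    all orderings with ``n_permutations="exhaustive"``.
    """
    if D1.ids != D2.ids:
        raise ValueError("distance matrices must share the same samples in order")
    n = len(D1)
    iu = np.triu_indices(n, k=1)
    x = D1.values[iu]
    r_obs = _pearson(x, D2.values[iu])

    if n_permutations == "exhaustive":
        total = 0
        exceed = 0
        for perm in iter_permutations(range(n)):
            perm = np.asarray(perm)
            r_perm = _pearson(x, D2.values[np.ix_(perm, perm)][iu])
            total += 1
            if r_perm >= r_obs - 1e-12:
                exceed += 1
        return r_obs, exceed / total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(int(n_permutations)):
        perm = rng.permutation(n)
        r_perm = _pearson(x, D2.values[np.ix_(perm, perm)][iu])
        if r_perm >= r_obs - 1e-12:
            exceed += 1
    return r_obs, (1 + exceed) / (1 + int(n_permutations))
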