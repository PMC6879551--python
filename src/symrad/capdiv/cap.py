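"""Constrained analysis of principal coordinates (db-RDA).

PCoA of the dissimilarity matrix (positive axes only), least-squares
projection of those coordinates onto the factor's centered indicator matrix,
and eigendecomposition of the fitted values.  Haplotype ("species") scores
are presence-weighted averages of sample scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..popstats.distance import DistanceMatrix
from ..popstats.ordination import pcoa


@dataclass
class CapResult:
    ids: list[str]
    sample_scores: pd.DataFrame  # samples x constrained axes (CAP1, CAP2, ...)
    eigenvalues: np.ndarray  # constrained axes
    haplotype_scores: pd.DataFrame  # haplotype columns x axes
    factor: pd.Series
    p: float | None = None

    @property
    def n_axes(self) -> int:
        return self.sample_scores.shape[1]


def cap(
    D: DistanceMatrix,
    matrix,
    factor,
    n_permutations: int = 0,
    seed: int | None = None,
    eps: float = 1e-9,
) -> CapResult:
    """Run db-RDA of ``D`` constrained by a categorical factor.

    ``matrix`` is the haplotype presence matrix the distances came from
    (used for haplotype scores; missing cells count as non-carrying).
    ``factor`` maps sample id -> level; a single-level factor is an error.
    With ``n_permutations > 0`` a permutation test of the constrained
    variance fraction is run and reported as ``p``.
    """
    factor = pd.Series(dict(factor)) if not isinstance(factor, pd.Series) else factor
    factor = factor.loc[D.ids]
    levels = pd.unique(factor)
    if len(levels) < 2:
        raise ValueError("CAP factor must have at least two levels")

    ord_res = pcoa(D)
    Y = ord_res.coordinates  # n x m, already column-centered

    # centered indicator matrix of the factor
    X = pd.get_dummies(factor).to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)

    # least-squares projection of Y onto span(X)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef

    # constrained axes from the fitted values
    U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
    keep = S > eps * max(1.0, S[0] if len(S) else 0.0)
    scores = U[:, keep] * S[keep]
    eigvals = (S[keep] ** 2)

    for j in range(scores.shape[1]):
        k = np.argmax(np.abs(scores[:, j]))
        if scores[k, j] < 0:
            scores[:, j] = -scores[:, j]

    axis_names = [f"CAP{i + 1}" for i in range(scores.shape[1])]
    sample_scores = pd.DataFrame(scores, index=D.ids, columns=axis_names)

    data = getattr(matrix, "data", matrix)
    P = data.loc[D.ids].fillna(0.0).to_numpy(dtype=float)
    carriers = P.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        hap = (P.T @ scores) / carriers[:, None]
    hap[carriers == 0] = np.nan
    haplotype_scores = pd.DataFrame(hap, index=data.columns, columns=axis_names)

    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        total = (Y**2).sum()
        stat_obs = (fitted**2).sum() / total
        exceed = 0
        n = len(D.ids)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            coef_p, *_ = np.linalg.lstsq(X[perm], Y, rcond=None)
            stat = ((X[perm] @ coef_p) ** 2).sum() / total
            if stat >= stat_obs - 1e-12:
                exceed += 1
        p_value = (1 + exceed) / (1 + n_permutations)

    return CapResult(
        ids=list(D.ids),
        sample_scores=sample_scores,
        eigenvalues=eigvals,
        haplotype_scores=haplotype_scores,
        factor=factor,
        p=p_value,
    )
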