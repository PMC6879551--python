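"""Pairwise dissimilarities with missing-data-aware (pairwise-complete) modes."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)

    def submatrix(self, ids) -> "DistanceMatrix":
        ids = list(ids)
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major (i<j) order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(list(frame.index), frame.to_numpy())


def _presence_frame(matrix) -> pd.DataFrame:
    data = getattr(matrix, "data", matrix)
    if not isinstance(data, pd.DataFrame):
        raise TypeError("expected a HaplotypeMatrix or DataFrame")
    return data


def bray_curtis(matrix, mode: str = "pairwise") -> DistanceMatrix:
    """Bray-Curtis dissimilarity on binary presence/absence rows.

    ``d(i,j) = 1 - 2*shared / (presences_i + presences_j)`` computed over
    the columns non-missing in both samples (``mode="pairwise"``, default) or
    over columns complete in all samples (``mode="complete"``).  A pair with
    no jointly observed presences gets d = 1 (logged).
    """
    frame = _presence_frame(matrix)
    if mode == "complete":
        frame = frame.dropna(axis=1)
    elif mode != "pairwise":
        raise ValueError("mode must be 'pairwise' or 'complete'")
    X = frame.to_numpy(dtype=float)
    if np.nanmax(X, initial=0.0) > 1.0 or np.nanmin(X, initial=0.0) < 0.0:
        raise ValueError("bray_curtis expects binary presence/absence cells")
    obs = (~np.isnan(X)).astype(float)
    P = np.nan_to_num(X)
    shared = P @ P.T
    totals = P @ obs.T + obs @ P.T  # presences of i and j over jointly observed cols
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * shared / totals
    empty = totals <= 0
    if empty.sum() > len(frame):  # more than the diagonal
        logger.warning("%d sample pairs share no observed presences; d set to 1",
                       int((empty.sum() - len(frame)) // 2))
    d[empty] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(list(frame.index), d)


def euclidean_genotype_distance(genotypes: pd.DataFrame, mode: str = "pairwise") -> DistanceMatrix:
    """Euclidean distance on 0/1/2 genotype rows.

    Missing cells are handled pairwise-complete with rescaling by
    ``sqrt(L / L_obs)`` so distances stay comparable across pairs
    (``mode="complete"`` restricts to columns with no missing data).
    A pair sharing zero observed loci is an error.
    """
    frame = genotypes
    if mode == "complete":
        frame = frame.dropna(axis=1)
    elif mode != "pairwise":
        raise ValueError("mode must be 'pairwise' or 'complete'")
    G = frame.to_numpy(dtype=float)
    L = G.shape[1]
    obs = (~np.isnan(G)).astype(float)
    Gz = np.nan_to_num(G)
    A = Gz**2
    sq = A @ obs.T + obs @ A.T - 2.0 * (Gz @ Gz.T)
    L_obs = obs @ obs.T
    off_diag = ~np.eye(len(frame), dtype=bool)
    if (L_obs[off_diag] == 0).any():
        raise ValueError("a sample pair shares no observed loci")
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = sq * (L / np.maximum(L_obs, 1))
    d = np.sqrt(np.clip(scaled, 0.0, None))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(frame.index), d)
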