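"""Principal coordinates analysis (metric multidimensional scaling)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import DistanceMatrix


@dataclass
class OrdinationResult:
    """PCoA embedding: axes ordered by descending eigenvalue."""

    ids: list[str]
    coordinates: np.ndarray  # n x n_positive_axes, column-centered
    eigenvalues: np.ndarray  # all n, signed, descending
    proportion_explained: np.ndarray  # per positive axis

    def coords_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Double-centered -0.5 * D^2 matrix."""
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(D: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Classical PCoA via eigendecomposition of the Gower-centered matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for eigenvalues
    above ``eps``; negative eigenvalues are reported unmodified (no
    correction).  Axis signs are fixed so each axis's largest-magnitude
    loading is positive.  Requires at least 3 samples.
    """
    n = len(D)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    B = gower_center(D.values)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > eps
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return OrdinationResult(
        ids=list(D.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )
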