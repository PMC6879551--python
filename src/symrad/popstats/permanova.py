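"""One-way PERMANOVA with free label permutation, plus pairwise comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

from .distance import DistanceMatrix


@dataclass
class PermanovaResult:
    df_among: int
    df_residual: int
    ss_among: float
    ss_residual: float
    ss_total: float
    f: float
    r2: float
    p: float
    n_permutations: int | str

    def as_row(self) -> dict:
        return {
            "DF": self.df_among, "SS": self.ss_among, "F": self.f,
            "R": self.r2, "P": self.p,
        }


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == g) for g in pd.unique(labels)]


def _ss_stats(d2: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * len(idx))
    return ss_total, ss_total - ss_within, ss_within


def _pseudo_f(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    n = d2.shape[0]
    g = len(groups)
    _, ss_among, ss_within = _ss_stats(d2, groups)
    if ss_within == 0.0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def _labels_array(D: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, (dict, pd.Series)):
        mapping = dict(groups)
        return np.array([mapping[s] for s in D.ids])
    labels = np.asarray(list(groups))
    if len(labels) != len(D):
        raise ValueError("groups length does not match distance matrix")
    return labels


def permanova(
    D: DistanceMatrix,
    groups,
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``groups`` is a label per sample (sequence aligned with ``D.ids`` or a
    mapping).  The p-value uses the (1 + exceedances)/(1 + N) estimator
    under free permutation of sample labels; pass
    ``n_permutations="exhaustive"`` to enumerate every distinct label
    arrangement instead (p = exceedances/total, identity included).
    Requires >= 2 groups, each with >= 2 members.
    """
    labels = _labels_array(D, groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    singletons = uniq[counts < 2]
    if len(singletons):
        raise ValueError(f"group(s) with fewer than 2 members: {list(singletons)}")

    d2 = D.values**2
    n, g = len(labels), len(uniq)
    groups_idx = _group_indices(labels)
    ss_total, ss_among, ss_within = _ss_stats(d2, groups_idx)
    f_obs = _pseudo_f(d2, groups_idx)

    if n_permutations == "exhaustive":
        seen = 0
        exceed = 0
        for perm in set(iter_permutations(range(n))):
            perm = np.asarray(perm)
            f_perm = _pseudo_f(d2, _group_indices(labels[perm]))
            seen += 1
            if f_perm >= f_obs - 1e-12:
                exceed += 1
        p = exceed / seen
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(int(n_permutations)):
            perm = rng.permutation(n)
            f_perm = _pseudo_f(d2, _group_indices(labels[perm]))
            if f_perm >= f_obs - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + int(n_permutations))

    return PermanovaResult(
        df_among=g - 1,
        df_residual=n - g,
        ss_among=ss_among,
        ss_residual=ss_within,
        ss_total=ss_total,
        f=f_obs,
        r2=ss_among / ss_total,
        p=p,
        n_permutations=n_permutations,
    )


def pairwise_permanova(
    D: DistanceMatrix,
    groups,
    n_permutations: int | str = 999,
    correction: str = "bonferroni",
    seed: int | None = None,
) -> pd.DataFrame:
    """PERMANOVA on every unordered pair of groups, with multiplicity correction.

    Returns a DataFrame with one row per pair (columns group1, group2, DF,
    SS, F, R, P, P_adj).  Corrections: ``bonferroni`` (default), ``holm``,
    ``bh`` (Benjamini–Hochberg).
    """
    labels = _labels_array(D, groups)
    uniq = list(pd.unique(labels))
    rng = np.random.default_rng(seed)
    rows = []
    for i, g1 in enumerate(uniq):
        for g2 in uniq[i + 1 :]:
            mask = np.isin(labels, [g1, g2])
            ids = [s for s, m in zip(D.ids, mask) if m]
            sub = D.submatrix(ids)
            sub_labels = labels[mask]
            res = permanova(
                sub, sub_labels, n_permutations=n_permutations,
                seed=int(rng.integers(2**31)),
            )
            rows.append({"group1": g1, "group2": g2, **res.as_row()})
    table = pd.DataFrame(rows)
    m = len(table)
    p = table["P"].to_numpy()
    if correction == "bonferroni":
        p_adj = np.minimum(1.0, p * m)
    elif correction == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        p_adj = adj
    elif correction == "bh":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, p[idx] * m / (rank + 1))
            adj[idx] = running
        p_adj = adj
    else:
        raise ValueError("correction must be bonferroni, holm or bh")
    table["P_adj"] = p_adj
    return table
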