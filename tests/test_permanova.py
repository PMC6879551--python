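from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from symrad.popstats import DistanceMatrix, permanova, pairwise_permanova


def naive_pseudo_f(values, labels):
    """Straight-from-the-definition pseudo-F with explicit double loops."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += values[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        members = [i for i in range(n) if labels[i] == g]
        s = 0.0
        for a, b in combinations(members, 2):
            s += values[a, b] ** 2
        ss_within += s / len(members)
    ss_among = ss_total - ss_within
    return (ss_among / (len(groups) - 1)) / (ss_within / (n - len(groups)))


def _random_D(rng, n):
    pts = rng.normal(size=(n, 3))
    return DistanceMatrix([f"s{i}" for i in range(n)], squareform(pdist(pts)))


def test_df_among_is_groups_minus_one(rng):
    D = _random_D(rng, 16)
    labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4 + ["d"] * 4
    res = permanova(D, labels, n_permutations=99, seed=0)
    assert res.df_among == 3
    assert res.df_residual == 12


def test_ss_decomposition_and_r2(rng):
    D = _random_D(rng, 12)
    labels = ["a"] * 6 + ["b"] * 6
    res = permanova(D, labels, n_permutations=99, seed=0)
    assert res.ss_among + res.ss_residual == pytest.approx(res.ss_total)
    assert 0.0 <= res.r2 <= 1.0
    assert res.f == pytest.approx(naive_pseudo_f(D.values, labels))


def test_perfect_separation():
    # two groups of 3, d=0 within, d=1 between
    n = 6
    values = np.ones((n, n))
    values[:3, :3] = 0.0
    values[3:, 3:] = 0.0
    np.fill_diagonal(values, 0.0)
    D = DistanceMatrix([f"s{i}" for i in range(n)], values)
    labels = ["a"] * 3 + ["b"] * 3
    res = permanova(D, labels, n_permutations="exhaustive")
    assert res.r2 == pytest.approx(1.0)
    # minimum achievable p: 2 of the C(6,3)=20 assignments reach the observed F
    assert res.p == pytest.approx(0.1)


def test_exhaustive_p_matches_enumeration(rng):
    # n=7, groups of 3 and 4: enumerate all C(7,3) label assignments
    D = _random_D(rng, 7)
    labels = np.array(["a"] * 3 + ["b"] * 4)
    res = permanova(D, labels, n_permutations="exhaustive")
    f_obs = naive_pseudo_f(D.values, list(labels))
    exceed = total = 0
    for members in combinations(range(7), 3):
        lab = np.array(["b"] * 7)
        lab[list(members)] = "a"
        total += 1
        if naive_pseudo_f(D.values, list(lab)) >= f_obs - 1e-12:
            exceed += 1
    assert res.p == pytest.approx(exceed / total)
    assert res.f == pytest.approx(f_obs)


def test_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    D = _random_D(rng, 20)
    labels = (["a"] * 5 + ["b"] * 5 + ["c"] * 10)
    ours = permanova(D, labels, n_permutations=99, seed=0)
    theirs = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(D.values, ids=D.ids), grouping=labels, permutations=0
    )
    assert ours.f == pytest.approx(theirs["test statistic"])


def test_p_floor_respected(rng):
    D = _random_D(rng, 12)
    labels = ["a"] * 6 + ["b"] * 6
    for n_perm in (9, 99):
        res = permanova(D, labels, n_permutations=n_perm, seed=1)
        assert res.p >= 1.0 / (1 + n_perm)


def test_singleton_group_rejected(rng):
    D = _random_D(rng, 5)
    with pytest.raises(ValueError, match="lonely"):
        permanova(D, ["a"] * 4 + ["lonely"], n_permutations=9)


def test_single_group_rejected(rng):
    D = _random_D(rng, 5)
    with pytest.raises(ValueError):
        permanova(D, ["a"] * 5, n_permutations=9)


def test_pairwise_six_rows_and_consistency(rng):
    D = _random_D(rng, 16)
    labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4 + ["d"] * 4
    table = pairwise_permanova(D, labels, n_permutations=49, seed=3)
    assert len(table) == 6
    # bonferroni with 6 tests
    np.testing.assert_allclose(
        table["P_adj"], np.minimum(1.0, table["P"] * 6)
    )
    # each pair's F equals a direct PERMANOVA on the extracted submatrix
    row = table.iloc[0]
    ids = [s for s, l in zip(D.ids, labels) if l in (row["group1"], row["group2"])]
    sub = D.submatrix(ids)
    sub_labels = [l for l in labels if l in (row["group1"], row["group2"])]
    direct = permanova(sub, sub_labels, n_permutations=9, seed=0)
    assert row["F"] == pytest.approx(direct.f)


def test_pairwise_corrections(rng):
    D = _random_D(rng, 12)
    labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    for corr in ("holm", "bh"):
        table = pairwise_permanova(D, labels, n_permutations=49, correction=corr, seed=0)
        assert ((table["P_adj"] >= table["P"] - 1e-12) & (table["P_adj"] <= 1.0)).all()
    with pytest.raises(ValueError):
        pairwise_permanova(D, labels, n_permutations=9, correction="fdr_by")
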