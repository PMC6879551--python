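import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from symrad.capdiv import cap, select_outlier_haplotypes
from symrad.popstats import DistanceMatrix, bray_curtis, pcoa


def _hapframe(X):
    cols = pd.MultiIndex.from_tuples(
        [(f"L{j}", "h0") for j in range(X.shape[1])], names=["locus", "hap"]
    )
    return pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])], columns=cols)


def _toy(rng, n_per=8, p=40, signal=10):
    """Two groups with group-diagnostic presence columns."""
    X = (rng.random((2 * n_per, p)) < 0.5).astype(float)
    X[:n_per, :signal] = 1.0
    X[n_per:, :signal] = 0.0
    frame = _hapframe(X)
    labels = pd.Series(
        ["g1"] * n_per + ["g2"] * n_per, index=frame.index, name="location"
    )
    return frame, labels


def test_single_level_factor_rejected(rng):
    frame, labels = _toy(rng)
    D = bray_curtis(frame)
    with pytest.raises(ValueError):
        cap(D, frame, pd.Series("same", index=frame.index))


def test_rank_bound_four_levels(rng):
    frame, _ = _toy(rng, n_per=10)
    labels = pd.Series(
        ["a", "b", "c", "d"] * 5, index=frame.index
    )
    D = bray_curtis(frame)
    res = cap(D, frame, labels)
    assert res.n_axes <= 3


def test_two_groups_single_axis_reproduces_separation(rng):
    # perfectly separated groups: rows identical within groups
    row_a = (rng.random(40) < 0.5).astype(float)
    row_b = 1.0 - row_a
    X = np.vstack([np.tile(row_a, (8, 1)), np.tile(row_b, (8, 1))])
    frame = _hapframe(X)
    labels = pd.Series(["g1"] * 8 + ["g2"] * 8, index=frame.index)
    D = bray_curtis(frame)
    res = cap(D, frame, labels)
    assert res.n_axes == 1
    ords = pcoa(D)
    r = np.corrcoef(res.sample_scores["CAP1"], ords.coordinates[:, 0])[0, 1]
    assert abs(r) > 0.99


def test_full_rank_constraint_reduces_to_pcoa(rng):
    pts = rng.normal(size=(10, 3))
    D = DistanceMatrix([f"s{i}" for i in range(10)], squareform(pdist(pts)))
    frame = _hapframe((rng.random((10, 20)) < 0.5).astype(float))
    factor = pd.Series([f"lvl{i}" for i in range(10)], index=frame.index)
    res = cap(D, frame, factor)
    recovered = squareform(pdist(res.sample_scores.to_numpy()))
    np.testing.assert_allclose(recovered, D.values, atol=1e-6)


def test_sample_scores_centered(rng):
    frame, labels = _toy(rng)
    D = bray_curtis(frame)
    res = cap(D, frame, labels)
    np.testing.assert_allclose(res.sample_scores.mean(axis=0), 0.0, atol=1e-9)


def test_haplotype_scores_presence_weighted(rng):
    frame, labels = _toy(rng)
    D = bray_curtis(frame)
    res = cap(D, frame, labels)
    scores = res.sample_scores.to_numpy()
    P = frame.to_numpy()
    j = 0  # diagnostic column present only in g1
    expected = scores[P[:, j] == 1.0, 0].mean()
    assert res.haplotype_scores.iloc[j, 0] == pytest.approx(expected)


def test_permutation_p_detects_structure(rng):
    frame, labels = _toy(rng)
    D = bray_curtis(frame)
    res = cap(D, frame, labels, n_permutations=99, seed=0)
    assert res.p == pytest.approx(0.01)


def test_diagnostic_haplotypes_are_outliers(rng):
    hits = 0
    reps = 10
    for rep in range(reps):
        # 600 noise columns so the 1% tails hold ~6 haplotypes each
        local = np.random.default_rng(1000 + rep)
        X = (local.random((30, 600)) < 0.5).astype(float)
        X[:15, :5] = 1.0
        X[15:, :5] = 0.0
        frame = _hapframe(X)
        labels = pd.Series(["g1"] * 15 + ["g2"] * 15, index=frame.index)
        D = bray_curtis(frame)
        res = cap(D, frame, labels)
        table = select_outlier_haplotypes(res, gap_factor=1.2)
        stage1 = set(l for l, _ in table.index)
        if {f"L{j}" for j in range(5)} <= stage1:
            hits += 1
    assert hits >= int(0.9 * reps)


def test_outlier_stage1_percentile_and_planted_extreme(rng):
    # symmetric scores with one planted extreme at 10x the 99th percentile
    scores = rng.normal(size=500)
    scores[0] = 10 * np.quantile(np.abs(scores), 0.99)
    frame_cols = pd.MultiIndex.from_tuples(
        [(f"L{j}", "h0") for j in range(500)], names=["locus", "hap"]
    )
    fake = pd.DataFrame(
        {"CAP1": scores, "CAP2": rng.normal(size=500) * 0.1}, index=frame_cols
    )
    from symrad.capdiv.cap import CapResult

    res = CapResult(ids=[], sample_scores=pd.DataFrame(columns=["CAP1", "CAP2"]),
                    eigenvalues=np.array([1.0, 0.5]), haplotype_scores=fake,
                    factor=pd.Series(dtype=object))
    table = select_outlier_haplotypes(res, gap_factor=2.0)
    selected = table[table["selected"]]
    assert list(selected.index) == [("L0", "h0")]


def test_pct_high_one_empty_stage1(rng):
    scores = rng.normal(size=500)
    cols = pd.MultiIndex.from_tuples(
        [(f"L{j}", "h0") for j in range(500)], names=["locus", "hap"]
    )
    fake = pd.DataFrame({"CAP1": scores, "CAP2": scores}, index=cols)
    from symrad.capdiv.cap import CapResult

    res = CapResult(ids=[], sample_scores=pd.DataFrame(columns=["CAP1", "CAP2"]),
                    eigenvalues=np.array([1.0]), haplotype_scores=fake,
                    factor=pd.Series(dtype=object))
    table = select_outlier_haplotypes(res, pct_high=1.0, pct_low=0.0)
    assert len(table) == 0


def test_gap_factor_monotone(rng):
    scores = rng.normal(size=300)
    scores[:5] = np.array([5.0, 6.0, 7.0, -5.0, -6.0])
    cols = pd.MultiIndex.from_tuples(
        [(f"L{j}", "h0") for j in range(300)], names=["locus", "hap"]
    )
    fake = pd.DataFrame({"CAP1": scores, "CAP2": scores * 0.5}, index=cols)
    from symrad.capdiv.cap import CapResult

    res = CapResult(ids=[], sample_scores=pd.DataFrame(columns=["CAP1", "CAP2"]),
                    eigenvalues=np.array([1.0]), haplotype_scores=fake,
                    factor=pd.Series(dtype=object))
    counts = []
    for gap in (1.0, 1.5, 2.0, 3.0, 10.0):
        table = select_outlier_haplotypes(res, gap_factor=gap)
        counts.append(int(table["selected"].sum()))
    assert counts == sorted(counts, reverse=True)


def test_few_haplotypes_warns(rng):
    cols = pd.MultiIndex.from_tuples(
        [(f"L{j}", "h0") for j in range(10)], names=["locus", "hap"]
    )
    fake = pd.DataFrame({"CAP1": rng.normal(size=10)}, index=cols)
    from symrad.capdiv.cap import CapResult

    res = CapResult(ids=[], sample_scores=pd.DataFrame(columns=["CAP1"]),
                    eigenvalues=np.array([1.0]), haplotype_scores=fake,
                    factor=pd.Series(dtype=object))
    with pytest.warns(UserWarning):
        table = select_outlier_haplotypes(res, n_axes=1)
    assert len(table) == 2  # top and bottom one
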