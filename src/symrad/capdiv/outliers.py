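"""Extreme-CAP-score outlier haplotype selection."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cap import CapResult


def select_outlier_haplotypes(
    cap_result: CapResult,
    pct_high: float = 0.99,
    pct_low: float = 0.01,
    gap_factor: float = 2.0,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Two-stage outlier selection on the first ``n_axes`` CAP axes.

    Stage 1 flags haplotypes beyond the per-axis ``pct_high``/``pct_low``
    score percentiles on either axis.  Stage 2 keeps those whose absolute
    score exceeds ``gap_factor`` times the magnitude of the percentile cut
    they crossed (the "clearly separated from the pack" rule).  With fewer
    than 100 scored haplotypes the percentile cut is degenerate; a warning
    is issued and the top/bottom haplotype per axis is used for stage 1.

    Returns a DataFrame indexed by (locus, hap) with per-axis scores, the
    axis/direction that flagged each candidate, and a ``selected`` column
    for the stage-2 outcome.
    """
    scores = cap_result.haplotype_scores.iloc[:, :n_axes].dropna(how="all")
    axes = list(scores.columns)
    few = len(scores) < 100
    if few:
        warnings.warn(
            f"only {len(scores)} haplotypes: percentile cut degenerate, "
            "falling back to rank-based top/bottom 1 per axis"
        )
    records = []
    for axis in axes:
        s = scores[axis].dropna()
        if few:
            # rank fallback: flag the single most extreme haplotype per tail;
            # the runner-up value stands in for the percentile cut magnitude
            hi_cut = s.nlargest(2).iloc[-1] if len(s) > 1 else s.max()
            lo_cut = s.nsmallest(2).iloc[-1] if len(s) > 1 else s.min()
            hi_hits = s.index[s == s.max()][:1]
            lo_hits = s.index[s == s.min()][:1]
        else:
            hi_cut = s.quantile(pct_high)
            lo_cut = s.quantile(pct_low)
            hi_hits = s.index[s > hi_cut]
            lo_hits = s.index[s < lo_cut]
        for idx in hi_hits:
            records.append((idx, axis, "high", s[idx], hi_cut))
        for idx in lo_hits:
            records.append((idx, axis, "low", s[idx], lo_cut))

    if not records:
        return pd.DataFrame(
            columns=["axis", "direction", "score", "cut", "selected"]
        )
    cand = pd.DataFrame(
        records, columns=["column", "axis", "direction", "score", "cut"]
    )
    cand["selected"] = np.abs(cand["score"]) > gap_factor * np.abs(cand["cut"])
    # one row per haplotype column: keep the most extreme flagging
    cand["extremity"] = np.abs(cand["score"])
    cand = (
        cand.sort_values(["selected", "extremity"], ascending=False)
        .drop_duplicates("column")
        .set_index("column")
        .drop(columns="extremity")
    )
    for axis in axes:
        cand[axis] = scores.loc[cand.index, axis].to_numpy()
    cand["locus"] = [c[0] for c in cand.index]
    return cand
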