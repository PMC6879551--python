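"""Within-light-organ strain diversity and its relationship to host size."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StrainCountResult:
    sample_id: str
    min_strain_count: int
    standard_length: float | None = None


def strain_count(
    matrix,
    lengths: dict[str, float] | pd.Series | None = None,
) -> list[StrainCountResult]:
    """Minimum strain count per sample: the max, over loci, of present haplotypes.

    Loci missing for a sample are ignored; a sample with every locus missing
    is excluded with a warning.  ``lengths`` optionally attaches host
    standard length for the regression.
    """
    counts = matrix.present_counts()  # samples x loci, NaN where missing
    lengths = pd.Series(lengths) if lengths is not None else None
    out: list[StrainCountResult] = []
    for sample, row in counts.iterrows():
        if row.isna().all():
            warnings.warn(f"sample {sample} has no observed loci; strain count undefined")
            continue
        k = int(row.max())
        sl = float(lengths[sample]) if lengths is not None and sample in lengths else None
        out.append(StrainCountResult(sample, k, sl))
    return out


@dataclass(frozen=True)
class RegressionResult:
    f: float
    df1: int
    df2: int
    r2: float
    r2_adj: float
    p: float
    slope: float
    intercept: float


def length_regression(results: list[StrainCountResult]) -> RegressionResult:
    """OLS of strain count on host standard length with the slope F-test.

    Closed-form simple linear regression; ``F = MS_model / MS_resid`` with
    (1, n-2) degrees of freedom, adjusted R^2 = 1 - (1-R^2)(n-1)/(n-2).
    """
    pairs = [(r.standard_length, r.min_strain_count) for r in results
             if r.standard_length is not None]
    if len(pairs) < 3:
        raise ValueError("length regression needs at least 3 samples with lengths")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("host lengths are constant; regression undefined")
    n = len(x)
    xc = x - x.mean()
    slope = float((xc * (y - y.mean())).sum() / (xc**2).sum())
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - fitted) ** 2).sum())
    ss_mod = ss_tot - ss_res
    df1, df2 = 1, n - 2
    if ss_res == 0.0:
        f = np.inf
        p = 0.0
        r2 = 1.0
    else:
        f = (ss_mod / df1) / (ss_res / df2)
        p = float(stats.f.sf(f, df1, df2))
        r2 = ss_mod / ss_tot if ss_tot > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(f=float(f), df1=df1, df2=df2, r2=r2, r2_adj=r2_adj,
                            p=p, slope=slope, intercept=intercept)
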