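"""The missing-data filter cascade producing the per-dataset analysis matrices.

Stages, applied to a symbiont haplotype-presence matrix:

1. keep loci with a call in at least ``presence_all`` (70%) of all samples;
2. keep loci with a call in at least ``presence_pop`` (50%) of the samples of
   *every* population (population = location x year sampling group);
3. split samples into the analysis datasets (each year across sites, plus the
   multi-year single-site series);
4. within each dataset, drop individuals with more than ``max_missing`` (15%)
   missing loci, then loci with more than ``max_missing`` missing individuals
   (single pass by default; ``iterate=True`` repeats stage 4 to a fixpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .matrix import HaplotypeMatrix


@dataclass
class CascadeResult:
    datasets: dict[str, HaplotypeMatrix] = field(default_factory=dict)
    #: the matrix after stages 1-2 (input for strain-diversity counts)
    core: HaplotypeMatrix | None = None
    report: pd.DataFrame | None = None


def _default_datasets(meta: pd.DataFrame) -> dict[str, pd.Index]:
    out: dict[str, pd.Index] = {}
    for year in sorted(meta["year"].unique()):
        sel = meta.index[meta["year"] == year]
        if len(sel):
            out[str(year)] = sel
    counts = meta.groupby("location")["year"].nunique()
    multi = counts[counts >= 3]
    for loc in multi.index:
        out[loc.lower() if isinstance(loc, str) else str(loc)] = meta.index[
            meta["location"] == loc
        ]
    return out


def filter_cascade(
    matrix: HaplotypeMatrix,
    meta: pd.DataFrame,
    presence_all: float = 0.70,
    presence_pop: float = 0.50,
    max_missing: float = 0.15,
    datasets: dict[str, pd.Index] | None = None,
    iterate: bool = False,
) -> CascadeResult:
    """Apply the four-stage cascade; see module docstring.

    ``meta`` must be indexed by sample id with ``location`` and ``year``
    columns.  Raises if stage 2 finds a population with no samples left or a
    dataset loses all its samples or loci.
    """
    meta = meta.loc[matrix.samples]
    rows = []

    observed = matrix.locus_observed()

    # stage 1: global presence
    keep1 = observed.columns[observed.mean(axis=0) >= presence_all]
    rows.append({"stage": "1_presence_all", "dataset": "all",
                 "n_samples": len(matrix.samples), "n_loci": len(keep1)})

    # stage 2: per-population presence
    pops = meta["location"].astype(str) + ":" + meta["year"].astype(str)
    keep2 = []
    for locus in keep1:
        ok = True
        for pop in pops.unique():
            members = pops.index[pops == pop]
            if len(members) == 0:
                raise RuntimeError(f"population {pop} has no samples")
            if observed.loc[members, locus].mean() < presence_pop:
                ok = False
                break
        if ok:
            keep2.append(locus)
    rows.append({"stage": "2_presence_pop", "dataset": "all",
                 "n_samples": len(matrix.samples), "n_loci": len(keep2)})

    core = matrix.subset_loci(keep2)

    # stage 3: dataset split
    if datasets is None:
        datasets = _default_datasets(meta)

    out: dict[str, HaplotypeMatrix] = {}
    for name, sample_idx in datasets.items():
        ds = core.subset_samples([s for s in core.samples if s in set(sample_idx)])
        rows.append({"stage": "3_split", "dataset": name,
                     "n_samples": len(ds.samples), "n_loci": ds.n_loci})

        # stage 4: individuals then loci with >max_missing missing
        while True:
            obs = ds.locus_observed()
            sample_missing = 1.0 - obs.mean(axis=1)
            ds = ds.subset_samples(sample_missing.index[sample_missing <= max_missing])
            obs = ds.locus_observed()
            locus_missing = 1.0 - obs.mean(axis=0)
            ds = ds.subset_loci(locus_missing.index[locus_missing <= max_missing])
            if not iterate:
                break
            obs = ds.locus_observed()
            if ((1.0 - obs.mean(axis=1)) <= max_missing).all() and (
                (1.0 - obs.mean(axis=0)) <= max_missing
            ).all():
                break
        if len(ds.samples) == 0 or ds.n_loci == 0:
            raise RuntimeError(f"dataset {name} was emptied by the filter cascade")
        rows.append({"stage": "4_missingness", "dataset": name,
                     "n_samples": len(ds.samples), "n_loci": ds.n_loci})
        out[name] = ds

    return CascadeResult(datasets=out, core=core, report=pd.DataFrame(rows))
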