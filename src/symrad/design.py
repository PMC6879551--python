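"""Default multi-site, multi-year sampling design emulated by the simulator.

The design is a list of (location id, location name, year, n samples) rows:
ten locations sampled in 2013, four in 2014 (three shared with 2013 plus one
distant island site, "K"), and one reef ("S") additionally sampled in 2012,
giving a three-year series at that site.  282 light-organ libraries in total.
"""

from __future__ import annotations

import pandas as pd

#: (location id, location name, year, number of samples)
STUDY_DESIGN: list[tuple[str, str, int, int]] = [
    ("S", "Sesoko", 2012, 16),
    ("S", "Sesoko", 2013, 18),
    ("S", "Sesoko", 2014, 21),
    ("M", "Motobu", 2013, 20),
    ("N", "Nago", 2013, 21),
    ("Hd", "Hedo", 2013, 17),
    ("It", "Itoman", 2013, 14),
    ("It", "Itoman", 2014, 27),
    ("O", "Ou", 2013, 16),
    ("Y", "Yonabaru", 2013, 16),
    ("Ik", "Ikei", 2013, 15),
    ("Ik", "Ikei", 2014, 22),
    ("Hk", "Henoko", 2013, 17),
    ("A", "Ada", 2013, 16),
    ("K", "Kume", 2014, 26),
]

#: Island-group membership used by the two-island simulation hierarchy:
#: every Okinawa-island site in one group, the distant Kume site in the other.
ISLAND_GROUPS: dict[str, str] = {
    "S": "okinawa", "M": "okinawa", "N": "okinawa", "Hd": "okinawa",
    "It": "okinawa", "O": "okinawa", "Y": "okinawa", "Ik": "okinawa",
    "Hk": "okinawa", "A": "okinawa", "K": "kume",
}


def study_metadata() -> pd.DataFrame:
    """Per-sample metadata table for the default design.

    Returns a DataFrame indexed by synthetic sample id with columns
    ``location``, ``year`` and ``group`` (island group). 282 rows.
    """
    rows = []
    for loc, _name, year, n in STUDY_DESIGN:
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{loc}{year}_{i:02d}",
                    "location": loc,
                    "year": year,
                    "group": ISLAND_GROUPS[loc],
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def dataset_samples(meta: pd.DataFrame, dataset: str) -> pd.DataFrame:
    """Subset metadata to one of the analysis datasets.

    ``"2013"`` and ``"2014"`` select all sites in that year; ``"sesoko"``
    selects location S across all years; ``"all"`` is the identity.
    """
    if dataset == "all":
        return meta
    if dataset in {"2013", "2014"}:
        return meta[meta["year"] == int(dataset)]
    if dataset.lower() == "sesoko":
        return meta[meta["location"] == "S"]
    raise ValueError(f"unknown dataset {dataset!r}")
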