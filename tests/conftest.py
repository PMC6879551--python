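from __future__ import annotations

import numpy as np
import pytest

from symrad.radproc.demux import ReadRecord
from symrad.simdata import SimConfig, simulate_dataset


def as_read_records(sim_reads):
    """Convert simulator reads to demux-input ReadRecords (keeps truth tags)."""
    return [
        ReadRecord(r.read_id, r.sequence, r.quality, comment=r.comment)
        for r in sim_reads
    ]


def truth_tag(read):
    """Parse a truth comment: (sample, strain, scaffold, anchor, strand, trunc)."""
    body = read.comment.split("truth:", 1)[1]
    parts = body.split("|")
    sample, strain, loc = parts[0], parts[1], parts[2]
    scaffold, anchor, strand = loc.rsplit(":", 2)
    return sample, strain, scaffold, int(anchor), strand, "trunc" in parts[3:]


SMALL_CFG = dict(
    n_scaffolds=4,
    scaffold_length=20_000,
    samples_per_site=4,
    strains_per_pool=6,
    k_min=2,
    k_max=5,
    host_n_scaffolds=2,
    host_scaffold_length=20_000,
    host_n_sites=30,
    depth_mean=40.0,
    host_depth_mean=20.0,
)


@pytest.fixture(scope="session")
def sim_small():
    """16 samples over 4 sites, error rate 0.001, host reads included."""
    return simulate_dataset(SimConfig(**SMALL_CFG, error_rate=0.001), seed=11)


@pytest.fixture(scope="session")
def sim_clean():
    """Same design, error-free (for exact truth audits)."""
    return simulate_dataset(SimConfig(**SMALL_CFG, error_rate=0.0), seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
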