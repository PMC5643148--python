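"""Shared fixtures: tiny in-memory record tables and small simulated samples."""

import pandas as pd
import pytest

from oometh import synthetic_methylome as sm
from oometh.io_formats import REPORT_COLUMNS

#: Small genome used by unit-level simulation tests: 30 windows, ~3k dyads.
SMALL_GENOME = (("chr1", 200_000), ("chr2", 100_000))


def make_records(rows):
    """Build a per-cytosine report frame from (chrom, pos, strand, m, u, ctx, tri)."""
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


@pytest.fixture
def simple_records():
    return make_records(
        [
            ("chr1", 1000, "+", 3, 1, "CG", "CGT"),
            ("chr1", 1001, "-", 0, 4, "CG", "CGA"),
            ("chr1", 1500, "+", 2, 2, "CG", "CGC"),
            ("chr1", 2000, "+", 1, 3, "CHG", "CAG"),
            ("chr1", 2500, "-", 0, 5, "CHH", "CTT"),
        ]
    )


@pytest.fixture(scope="session")
def small_fgo():
    """A small control FGO sample shared across read-only tests."""
    cfg = sm.control_fgo_config(seed=11, genome_spec=SMALL_GENOME, noncg_density=40.0)
    records, truth = sm.simulate_oocyte_methylome(cfg, "FGO")
    return cfg, records, truth
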