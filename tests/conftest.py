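import numpy as np
import pandas as pd
import pytest

from cisclone import CISLocusSpec, GenomeLayout, SimConfig, simulate_cohort

SMALL_GENOME = GenomeLayout(names=("chr1", "chr2"), lengths=(50_000_000, 50_000_000))

SMALL_LOCI = (
    CISLocusSpec("locA", "chr1", 10_000_000, 3_000, "early", 0.5),
    CISLocusSpec("locB", "chr1", 30_000_000, 3_000, "early", 0.3),
    CISLocusSpec("locC", "chr2", 10_000_000, 3_000, "mid", 0.4),
    CISLocusSpec("locD", "chr2", 30_000_000, 3_000, "late", 0.3),
)


def small_config(**overrides) -> SimConfig:
    kwargs = dict(
        genome=SMALL_GENOME,
        loci=SMALL_LOCI,
        group_order=("early", "mid", "late"),
        n_tumors=60,
        background_rate=5.0,
        lp_depth=40.0,
        exclusivity=True,
        seed=11,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    config = small_config()
    fragments, truth = simulate_cohort(config)
    return config, fragments, truth


def make_fragments(rows) -> pd.DataFrame:
    """rows: (tumor_id, chrom, position, ligation_point, orientation)."""
    return pd.DataFrame(
        rows, columns=["tumor_id", "chrom", "position", "ligation_point", "orientation"]
    )


def make_insertions(rows) -> pd.DataFrame:
    """rows: (tumor_id, chrom, position, orientation, lp_count, read_count)."""
    return pd.DataFrame(
        rows,
        columns=["tumor_id", "chrom", "position", "orientation", "lp_count", "read_count"],
    )
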