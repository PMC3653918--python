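"""Insertion calling from fragment records, LP counting and background filtering.

A called insertion groups the junction fragments of one proviral integration
in one tumor. The number of distinct ligation points (LPs) in the group is a
relative clonality measure: an insertion with n distinct LPs was present in
at least n independent cells. Insertions supported by a single LP are
indistinguishable from one-cell background events and are removed by
:func:`filter_single_lp`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd

from .io import FRAGMENT_COLUMNS, INSERTION_COLUMNS

_KEY = ["tumor_id", "chrom", "orientation"]


def call_insertions(fragments: pd.DataFrame, merge_window: int = 5) -> pd.DataFrame:
    """Cluster fragments into insertion calls.

    Fragments from the same tumor, chromosome and orientation whose junction
    positions differ by at most ``merge_window`` bp are one insertion.
    The representative position is the modal junction position of the
    cluster (ties broken toward the smaller coordinate); lp_count is the
    number of distinct ligation points and read_count the cluster size.
    Order-independent: any row permutation of the input yields the same calls.
    """
    if merge_window < 0:
        raise ValueError("merge_window must be >= 0")
    if fragments.empty:
        return pd.DataFrame(columns=INSERTION_COLUMNS)
    df = fragments[FRAGMENT_COLUMNS].sort_values(
        _KEY + ["position", "ligation_point"], kind="mergesort"
    )
    same_key = (df[_KEY] == df[_KEY].shift()).all(axis=1)
    gap_ok = df["position"].diff() <= merge_window
    new_cluster = ~(same_key & gap_ok)
    df = df.assign(_cluster=new_cluster.cumsum())

    agg = df.groupby("_cluster", sort=True).agg(
        tumor_id=("tumor_id", "first"),
        chrom=("chrom", "first"),
        orientation=("orientation", "first"),
        lp_count=("ligation_point", "nunique"),
        read_count=("position", "size"),
    )
    # modal position per cluster, smallest coordinate on ties
    pos_counts = (
        df.groupby(["_cluster", "position"], sort=True)
        .size()
        .reset_index(name="n")
        .sort_values(["_cluster", "n", "position"], ascending=[True, False, True], kind="mergesort")
        .drop_duplicates("_cluster")
        .set_index("_cluster")["position"]
    )
    agg["position"] = pos_counts
    out = agg.reset_index(drop=True)[INSERTION_COLUMNS]
    return out.sort_values(
        ["tumor_id", "chrom", "position", "orientation"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class FilterResult:
    """Post-filter insertions plus tumors that lost all their insertions."""

    insertions: pd.DataFrame
    dropped_tumors: list[str] = field(default_factory=list)
    min_lp: int = 2


def filter_single_lp(insertions: pd.DataFrame, min_lp: int = 2) -> FilterResult:
    """Retain insertions with lp_count >= min_lp (default: discard single-LP).

    Tumors whose insertions are all below the cutoff are flagged in
    ``dropped_tumors`` so run reports can account for them.
    """
    kept = insertions[insertions["lp_count"] >= min_lp].reset_index(drop=True)
    before_tumors = set(insertions["tumor_id"])
    after_tumors = set(kept["tumor_id"])
    return FilterResult(
        insertions=kept,
        dropped_tumors=sorted(before_tumors - after_tumors),
        min_lp=min_lp,
    )


@dataclass
class CohortSummary:
    n_sites_before: int
    n_sites_after: int
    n_tumors_before: int
    n_tumors_after: int
    reads_before: int
    reads_after: int
    site_reduction_pct: float | None
    read_reduction_pct: float | None

    @property
    def site_reduction_pct_int(self) -> int | None:
        """Integer display value; floored so a reduction is never overstated."""
        return None if self.site_reduction_pct is None else floor(self.site_reduction_pct)

    @property
    def read_reduction_pct_int(self) -> int | None:
        return None if self.read_reduction_pct is None else floor(self.read_reduction_pct)

    def as_dict(self) -> dict:
        return {
            "n_sites_before": self.n_sites_before,
            "n_sites_after": self.n_sites_after,
            "n_tumors_before": self.n_tumors_before,
            "n_tumors_after": self.n_tumors_after,
            "reads_before": self.reads_before,
            "reads_after": self.reads_after,
            "site_reduction_pct": self.site_reduction_pct_int,
            "read_reduction_pct": self.read_reduction_pct_int,
        }


def cohort_summary(after: pd.DataFrame, before: pd.DataFrame) -> CohortSummary:
    """Site and read reductions of the LP filter, as printed in run reports.

    Percent reduction is 100 x (1 - after/before); the integer report value
    is floored. An empty pre-filter cohort yields not-applicable (None)
    percentages.
    """
    n_before, n_after = len(before), len(after)
    reads_before = int(before["read_count"].sum()) if n_before else 0
    reads_after = int(after["read_count"].sum()) if n_after else 0
    site_pct = None if n_before == 0 else 100.0 * (n_before - n_after) / n_before
    read_pct = None if reads_before == 0 else 100.0 * (reads_before - reads_after) / reads_before
    return CohortSummary(
        n_sites_before=n_before,
        n_sites_after=n_after,
        n_tumors_before=before["tumor_id"].nunique() if n_before else 0,
        n_tumors_after=after["tumor_id"].nunique() if n_after else 0,
        reads_before=reads_before,
        reads_after=reads_after,
        site_reduction_pct=site_pct,
        read_reduction_pct=read_pct,
    )


def cross_contamination_filter(
    fragments: pd.DataFrame, pools: dict[str, str] | None = None
) -> pd.DataFrame:
    """Optional barcode-bleed control for pooled sequencing runs.

    An identical (chrom, position, ligation_point) triple observed in more
    than one tumor of the same pool is almost certainly cross-contamination;
    only the tumor with the most supporting fragments at that insertion
    keeps the triple (ties toward the lexicographically smaller tumor id).
    ``pools`` maps tumor_id -> pool name; by default all tumors share one
    pool. Off by default in the pipeline.
    """
    if fragments.empty:
        return fragments.copy()
    df = fragments.copy()
    df["_pool"] = df["tumor_id"].map(pools) if pools else "pool0"
    support = (
        df.groupby(["tumor_id", "chrom", "position"], sort=False)
        .size()
        .rename("_support")
    )
    df = df.join(support, on=["tumor_id", "chrom", "position"])
    best = (
        df.sort_values(["_support", "tumor_id"], ascending=[False, True], kind="mergesort")
        .drop_duplicates(["_pool", "chrom", "position", "ligation_point"])
        .set_index(["_pool", "chrom", "position", "ligation_point"])["tumor_id"]
    )
    owner = best.reindex(
        pd.MultiIndex.from_frame(df[["_pool", "chrom", "position", "ligation_point"]])
    ).to_numpy()
    kept = df[df["tumor_id"].to_numpy() == owner]
    return kept[FRAGMENT_COLUMNS].reset_index(drop=True)
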