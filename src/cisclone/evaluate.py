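"""Scoring pipeline output against the planted truth of a synthetic cohort.

Used by the validation suites: CIS detection is scored as sensitivity
(planted loci overlapped by a detected region) and precision (detected
regions overlapping a planted locus), and the progression model as the
fraction of sufficiently co-occurring group pairs whose majority clonality
direction matches the planted temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calling import call_insertions, filter_single_lp
from .cis import CISRegion, assign_targets, detect_cis, DEFAULT_SCALES
from .network import build_incidence
from .progression import OrderComparison, all_comparisons, group_cis, group_scores
from .simulate import SimConfig, SimTruth, simulate_cohort


@dataclass
class DetectionScore:
    n_planted: int
    n_detected: int
    n_planted_recovered: int
    n_detected_matching: int

    @property
    def sensitivity(self) -> float:
        return self.n_planted_recovered / self.n_planted if self.n_planted else float("nan")

    @property
    def precision(self) -> float:
        return self.n_detected_matching / self.n_detected if self.n_detected else float("nan")


def score_cis_detection(regions: list[CISRegion], truth: SimTruth) -> DetectionScore:
    """Overlap-based match between detected regions and planted intervals."""
    intervals = truth.intervals
    recovered = 0
    for _, row in intervals.iterrows():
        if any(
            r.chrom == row["chrom"] and r.start <= row["end"] and r.end >= row["start"]
            for r in regions
        ):
            recovered += 1
    matching = 0
    for r in regions:
        sub = intervals[intervals["chrom"] == r.chrom]
        if any(
            (r.start <= e) and (r.end >= s) for s, e in zip(sub["start"], sub["end"])
        ):
            matching += 1
    return DetectionScore(
        n_planted=len(intervals),
        n_detected=len(regions),
        n_planted_recovered=recovered,
        n_detected_matching=matching,
    )


def truth_stage_of_groups(
    groups, regions: list[CISRegion], truth: SimTruth
) -> dict[str, int]:
    """Map analysis group names onto planted temporal-order positions.

    Family groups are matched by name against the planted group order;
    singleton groups (named by CIS id) are matched through the assigned
    target gene's planted family. Groups built on false-positive regions
    have no stage and are omitted.
    """
    order = {g: i for i, g in enumerate(truth.group_order)}
    locus_group = {l.name: l.group for l in truth.loci}
    target_of = {r.cis_id: r.target for r in regions}
    stages: dict[str, int] = {}
    for g in groups:
        if g.name in order:
            stages[g.name] = order[g.name]
            continue
        target = target_of.get(g.name)
        planted = locus_group.get(target) if target else None
        if planted in order:
            stages[g.name] = order[planted]
    return stages


def score_order_recovery(
    comparisons: list[OrderComparison],
    stages: dict[str, int],
    min_informative: int = 10,
) -> tuple[int, int]:
    """(correct, evaluated) majority-direction calls among co-occurring pairs.

    A pair is evaluated when both groups map to distinct planted stages and
    co-occurs informatively in at least ``min_informative`` tumors; it is
    correct when the group winning more tumors is the planted-earlier one.
    """
    correct = evaluated = 0
    for c in comparisons:
        if c.untestable or c.n_informative < min_informative:
            continue
        sa, sb = stages.get(c.group_a), stages.get(c.group_b)
        if sa is None or sb is None or sa == sb or c.wins_a == c.wins_b:
            continue
        evaluated += 1
        earlier_is_a = sa < sb
        if (c.wins_a > c.wins_b) == earlier_is_a:
            correct += 1
    return correct, evaluated


def run_replicate(
    sim_config: SimConfig,
    families: dict[str, list[str]],
    scales=DEFAULT_SCALES,
    alpha: float = 0.05,
    n_perm: int = 200,
    min_group_tumors: int = 10,
):
    """Simulate one cohort and run the full chain; returns the pieces needed
    for truth-based scoring: (truth, insertions, regions, comparisons, stages)."""
    from .pipeline import _family_map_for_cis, _truth_annotation

    fragments, truth = simulate_cohort(sim_config)
    insertions = filter_single_lp(call_insertions(fragments)).insertions
    regions = detect_cis(
        insertions,
        sim_config.genome.sizes,
        scales=scales,
        alpha=alpha,
        n_perm=n_perm,
        seed=sim_config.seed,
    )
    regions = assign_targets(regions, _truth_annotation(truth))
    matrix = build_incidence(insertions, regions, truth.tumors)
    family_map = _family_map_for_cis(regions, families)
    groups = group_cis(matrix, family_map, min_tumors=min_group_tumors)
    comparisons = all_comparisons(group_scores(matrix, groups))
    stages = truth_stage_of_groups(groups, regions, truth)
    return truth, insertions, regions, comparisons, stages
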