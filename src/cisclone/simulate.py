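"""Synthetic insertional-mutagenesis cohorts with known ground truth.

The generator emulates a retroviral screen read out by shear/splinkerette
sequencing: each tumor accumulates proviral insertions near a set of planted
driver loci (organised into gene families that are hit mutually exclusively)
plus a heavy load of background insertions. Clonality is encoded through the
number of distinct ligation points (LPs): an insertion present in many tumor
cells yields many distinct shear points, so early (low-rank) events are
planted with high LP counts and late events with low ones. Every insertion
with k ligation points emits at least k fragment records sharing one
insertion coordinate but k distinct ligation-point coordinates.

The returned truth object records every planted event (locus, rank, clonal
fraction, LP count) so downstream callers, CIS detection, exclusivity tests
and progression ordering can all be scored against the planted answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FRAGMENT_COLUMNS

#: shear fragments span this offset range from the viral junction (bp)
SHEAR_MIN, SHEAR_MAX = 100, 1000


@dataclass(frozen=True)
class GenomeLayout:
    """Named chromosomes with lengths in bp."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def length_of(self, chrom: str) -> int:
        return self.sizes[chrom]


@dataclass(frozen=True)
class CISLocusSpec:
    """A planted driver locus.

    spread is the standard deviation (bp) of insertion placement around the
    locus center; hit_probability is the per-tumor chance that this locus is
    mutated (before any within-family exclusivity thinning).
    """

    name: str
    chrom: str
    center: int
    spread: float
    group: str
    hit_probability: float

    def __post_init__(self):
        if not (0.0 <= self.hit_probability <= 1.0):
            raise ValueError(f"{self.name}: hit_probability outside [0, 1]")
        if self.spread <= 0:
            raise ValueError(f"{self.name}: spread must be positive")

    @property
    def interval(self) -> tuple[int, int]:
        """Planted region: center +/- 4 spread (covers ~all placements)."""
        half = int(round(4 * self.spread))
        return (max(1, self.center - half), self.center + half)


@dataclass
class SimConfig:
    genome: GenomeLayout
    loci: tuple[CISLocusSpec, ...]
    group_order: tuple[str, ...]
    n_tumors: int = 600
    strata: tuple[tuple[str, str, float], ...] = ()  # (strain, genotype, proportion)
    background_rate: float = 49.0
    clonal_fraction_by_rank: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125, 0.0625)
    lp_depth: float = 40.0
    mean_reads_per_lp: float = 1.5
    bg_single_lp_prob: float = 0.8
    exclusivity: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_tumors <= 0:
            raise ValueError("n_tumors must be positive")
        if not self.loci:
            raise ValueError("loci list must not be empty")
        cf = self.clonal_fraction_by_rank
        if cf[0] != 1.0 or any(b >= a for a, b in zip(cf, cf[1:])):
            raise ValueError("clonal_fraction_by_rank must start at 1.0 and strictly decrease")
        sizes = self.genome.sizes
        for locus in self.loci:
            if locus.chrom not in sizes:
                raise ValueError(f"{locus.name}: unknown chromosome {locus.chrom}")
            if not (1 <= locus.center <= sizes[locus.chrom]):
                raise ValueError(f"{locus.name}: center outside chromosome")
        groups = {locus.group for locus in self.loci}
        missing = groups - set(self.group_order)
        if missing:
            raise ValueError(f"groups missing from group_order: {sorted(missing)}")
        if not self.strata:
            self.strata = (("strainA", "wt", 1.0),)

    @property
    def groups(self) -> dict[str, list[str]]:
        """group name -> member locus names."""
        out: dict[str, list[str]] = {}
        for locus in self.loci:
            out.setdefault(locus.group, []).append(locus.name)
        return out

    @property
    def expected_events_per_tumor(self) -> float:
        """Mean planted events per tumor implied by the locus hit probabilities
        (an upper bound when within-family exclusivity thinning is on)."""
        return float(sum(l.hit_probability for l in self.loci))

    def clonal_fraction(self, rank: int) -> float:
        """Clonal fraction for a 1-based event rank; halves beyond the table."""
        cf = self.clonal_fraction_by_rank
        if rank <= len(cf):
            return cf[rank - 1]
        return cf[-1] * 0.5 ** (rank - len(cf))


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    events: pd.DataFrame  # tumor_id, locus, group, rank, clonal_fraction, lp_count, chrom, position
    loci: tuple[CISLocusSpec, ...]
    group_order: tuple[str, ...]
    tumors: pd.DataFrame  # tumor_id, strain, genotype
    n_background: int

    @property
    def intervals(self) -> pd.DataFrame:
        rows = [
            (l.name, l.group, l.chrom, *l.interval, l.center, l.hit_probability)
            for l in self.loci
        ]
        return pd.DataFrame(
            rows, columns=["locus", "group", "chrom", "start", "end", "center", "hit_probability"]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_order": list(self.group_order),
            "loci": [dataclasses.asdict(l) for l in self.loci],
            "tumors": self.tumors.to_dict(orient="records"),
            "events": self.events.to_dict(orient="records"),
            "n_background": int(self.n_background),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        loci = tuple(CISLocusSpec(**d) for d in payload["loci"])
        return cls(
            events=pd.DataFrame(payload["events"]),
            loci=loci,
            group_order=tuple(payload["group_order"]),
            tumors=pd.DataFrame(payload["tumors"]),
            n_background=payload["n_background"],
        )


def _assign_strata(config: SimConfig) -> pd.DataFrame:
    """Deterministic largest-remainder allocation of tumors to cohorts."""
    props = np.array([p for _, _, p in config.strata], dtype=float)
    props = props / props.sum()
    raw = props * config.n_tumors
    counts = np.floor(raw).astype(int)
    remainder = config.n_tumors - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    rows = []
    i = 0
    for (strain, genotype, _), k in zip(config.strata, counts):
        for _ in range(k):
            rows.append((f"T{i + 1:04d}", strain, genotype))
            i += 1
    return pd.DataFrame(rows, columns=["tumor_id", "strain", "genotype"])


def _draw_lp_count(rng: np.random.Generator, mean: float) -> int:
    # 1 + Poisson(mean - 1), floored at 1: every insertion has >= 1 fragment
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate fragment records and ground truth for one cohort.

    Deterministic given ``config.seed``. Returns the fragment table (one row
    per sequenced junction fragment) and the :class:`SimTruth`.
    """
    rng = np.random.default_rng(config.seed)
    tumors = _assign_strata(config)
    sizes = config.genome.sizes
    loci = config.loci
    order_index = {g: i for i, g in enumerate(config.group_order)}
    locus_p = np.array([l.hit_probability for l in loci])

    frag_rows: list[tuple] = []
    event_rows: list[tuple] = []
    n_background_total = 0

    def emit_fragments(tumor_id: str, chrom: str, position: int, orientation: str, lp: int):
        offsets = rng.choice(np.arange(SHEAR_MIN, SHEAR_MAX + 1), size=lp, replace=False)
        side = 1 if orientation == "+" else -1
        for off in np.sort(offsets):
            ligation = position + side * int(off)
            reads = 1 + int(rng.poisson(max(config.mean_reads_per_lp - 1.0, 0.0)))
            for _ in range(reads):
                frag_rows.append((tumor_id, chrom, position, ligation, orientation))

    for tumor_id in tumors["tumor_id"]:
        # --- planted driver events ---
        hit = rng.random(len(loci)) < locus_p
        hit_by_group: dict[str, list[int]] = {}
        for i in np.flatnonzero(hit):
            hit_by_group.setdefault(loci[i].group, []).append(int(i))
        chosen: dict[str, int] = {}
        for group, members in hit_by_group.items():
            if config.exclusivity and len(members) > 1:
                w = locus_p[members] / locus_p[members].sum()
                chosen[group] = int(rng.choice(members, p=w))
            elif config.exclusivity:
                chosen[group] = members[0]
        if config.exclusivity:
            events = sorted(chosen.items(), key=lambda kv: order_index[kv[0]])
            event_loci = [i for _, i in events]
        else:
            event_loci = sorted(np.flatnonzero(hit), key=lambda i: order_index[loci[i].group])
        for rank, i in enumerate(event_loci, start=1):
            locus = loci[i]
            cf = config.clonal_fraction(rank)
            lp = _draw_lp_count(rng, config.lp_depth * cf)
            length = sizes[locus.chrom]
            pos = int(round(rng.normal(locus.center, locus.spread)))
            pos = int(np.clip(pos, SHEAR_MAX + 1, length - SHEAR_MAX))
            orientation = "+" if rng.random() < 0.5 else "-"
            emit_fragments(tumor_id, locus.chrom, pos, orientation, lp)
            event_rows.append(
                (tumor_id, locus.name, locus.group, rank, cf, lp, locus.chrom, pos)
            )

        # --- background insertions, mostly single-LP ---
        n_bg = int(rng.poisson(config.background_rate))
        n_background_total += n_bg
        if n_bg:
            lengths = np.array([sizes[c] for c in config.genome.names], dtype=float)
            chrom_idx = rng.choice(len(lengths), size=n_bg, p=lengths / lengths.sum())
            for ci in chrom_idx:
                chrom = config.genome.names[ci]
                pos = int(rng.integers(SHEAR_MAX + 1, sizes[chrom] - SHEAR_MAX))
                lp = int(rng.geometric(config.bg_single_lp_prob))
                orientation = "+" if rng.random() < 0.5 else "-"
                emit_fragments(tumor_id, chrom, pos, orientation, lp)

    fragments = pd.DataFrame(frag_rows, columns=FRAGMENT_COLUMNS)
    fragments = fragments.sort_values(FRAGMENT_COLUMNS, kind="mergesort").reset_index(drop=True)
    events = pd.DataFrame(
        event_rows,
        columns=["tumor_id", "locus", "group", "rank", "clonal_fraction", "lp_count", "chrom", "position"],
    )
    truth = SimTruth(
        events=events,
        loci=loci,
        group_order=config.group_order,
        tumors=tumors,
        n_background=n_background_total,
    )
    return fragments, truth
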