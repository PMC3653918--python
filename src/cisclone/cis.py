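"""Common-insertion-site detection by Gaussian kernel convolution (GKC).

Insertion coordinates on a chromosome are smoothed with an unnormalized
Gaussian kernel, f(g) = sum_i exp(-(g - x_i)^2 / (2 h^2)), so an isolated
insertion contributes exactly 1.0 at its own coordinate and k coincident
insertions produce a peak of height k. Contributions are truncated beyond
4h of an insertion (the omitted tail mass is ~6e-5 of a kernel).

Significance is calibrated by permutation: the same number of insertions is
placed uniformly on the chromosome and the maximum smoothed peak recorded;
the empirical (1 - alpha) quantile of that max-peak null controls the
family-wise error rate per chromosome and scale. Contiguous grid runs above
the threshold become candidate regions; regions found at different kernel
widths that overlap are merged into one CIS, reported at the smallest
contributing scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

TRUNCATION_SIGMAS = 4.0

#: permutation thresholds are pure functions of their key (the child seed is
#: derived from it), so they are memoized across detect_cis calls
_THRESHOLD_CACHE: dict[tuple, float] = {}


@dataclass(frozen=True)
class KernelScale:
    """Kernel width h (bp) and grid spacing; grid defaults to h/10."""

    h: float
    grid_step: float | None = None

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("kernel width h must be positive")
        if self.grid_step is None:
            object.__setattr__(self, "grid_step", self.h / 10.0)
        if self.grid_step > self.h:
            raise ValueError("grid_step must not exceed h")


DEFAULT_SCALES = (KernelScale(10_000.0), KernelScale(30_000.0), KernelScale(100_000.0))


@dataclass
class DensityTrack:
    """Smoothed insertion intensity at the active grid points of one chromosome.

    Only grid points within 4h of at least one insertion are stored; the
    density is identically zero elsewhere.
    """

    chrom: str
    grid: np.ndarray  # bp coordinates, sorted
    values: np.ndarray
    grid_index: np.ndarray  # integer index of each point on the anchored grid
    scale: KernelScale

    def __post_init__(self):
        if len(self.grid) != len(self.values):
            raise ValueError("grid and values must have equal length")


@dataclass
class CISRegion:
    """A significant common insertion site (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    peak: int
    scale: float
    n_insertions: int
    n_tumors: int
    threshold: float
    target: str | None = None

    @property
    def cis_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _kernel_contributions(positions: np.ndarray, scale: KernelScale):
    """(grid indices, kernel values) of every insertion's truncated kernel."""
    h, step = scale.h, scale.grid_step
    reach = int(math.ceil(TRUNCATION_SIGMAS * h / step))
    centers = np.rint((positions - 1) / step).astype(np.int64)
    idx = centers[:, None] + np.arange(-reach, reach + 1)[None, :]
    g = 1.0 + idx * step
    d = g - positions[:, None]
    vals = np.exp(-(d * d) / (2.0 * h * h))
    vals[np.abs(d) > TRUNCATION_SIGMAS * h] = 0.0
    vals[idx < 0] = 0.0
    idx = np.maximum(idx, 0)
    return idx, vals


def kernel_density(
    positions, scale: KernelScale, chrom_length: int, chrom: str = ""
) -> DensityTrack:
    """Smoothed insertion density of one chromosome at one kernel scale.

    ``positions`` are 1-based insertion coordinates; a position outside
    [1, chrom_length] is rejected. The evaluation grid is anchored at
    coordinate 1 with spacing ``scale.grid_step``.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size and (positions.min() < 1 or positions.max() > chrom_length):
        raise ValueError("insertion position outside [1, chrom_length]")
    if positions.size == 0:
        empty = np.array([])
        return DensityTrack(chrom, empty, empty, empty.astype(np.int64), scale)
    idx, vals = _kernel_contributions(positions, scale)
    n_grid = int((chrom_length - 1) // scale.grid_step) + 1
    keep = idx < n_grid
    flat_idx = idx[keep]
    flat_vals = vals[keep]
    uniq, inverse = np.unique(flat_idx, return_inverse=True)
    density = np.bincount(inverse, weights=flat_vals, minlength=len(uniq))
    grid = 1.0 + uniq * scale.grid_step
    return DensityTrack(chrom, grid, density, uniq, scale)


def _max_peak(positions: np.ndarray, scale: KernelScale, chrom_length: int) -> float:
    """Maximum smoothed density, evaluated on the grid and at the exact
    insertion coordinates (so an isolated kernel attains its full height)."""
    if positions.size == 0:
        return 0.0
    idx, vals = _kernel_contributions(positions, scale)
    n_grid = int((chrom_length - 1) // scale.grid_step) + 1
    keep = idx < n_grid
    dens = np.bincount(idx[keep].ravel(), weights=vals[keep].ravel(), minlength=n_grid)
    peak = float(dens.max())
    # density at the insertion coordinates themselves, via neighbor windows
    order = np.sort(positions.astype(float))
    h = scale.h
    lo = np.searchsorted(order, order - TRUNCATION_SIGMAS * h, side="left")
    hi = np.searchsorted(order, order + TRUNCATION_SIGMAS * h, side="right")
    counts = hi - lo
    flat_j = np.repeat(np.arange(len(order)), counts)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    flat_i = np.arange(counts.sum()) - np.repeat(offsets, counts) + np.repeat(lo, counts)
    d = order[flat_i] - order[flat_j]
    sums = np.bincount(flat_j, weights=np.exp(-(d * d) / (2 * h * h)), minlength=len(order))
    return max(peak, float(sums.max()))


def null_peak_threshold(
    n: int,
    chrom_length: int,
    scale: KernelScale,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation-calibrated peak-height threshold for one chromosome/scale.

    Places ``n`` insertions uniformly on [1, chrom_length] ``n_perm`` times,
    records each permutation's maximum peak, and returns the empirical
    (1 - alpha) quantile, giving per-chromosome FWER control at ``alpha``.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be inside (0, 1)")
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        positions = rng.integers(1, chrom_length + 1, size=n).astype(float)
        maxima[p] = _max_peak(positions, scale, chrom_length)
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def _regions_above(track: DensityTrack, threshold: float) -> list[tuple[int, int, int]]:
    """Contiguous grid runs above threshold -> (start, end, peak) in bp."""
    above = track.values > threshold
    if not above.any():
        return []
    idx = track.grid_index[above]
    grid = track.grid[above]
    vals = track.values[above]
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    out = []
    for s, e in zip(starts, ends):
        seg_vals = vals[s : e + 1]
        peak = grid[s + int(np.argmax(seg_vals))]  # argmax -> first = smallest coord
        out.append((int(round(grid[s])), int(round(grid[e])), int(round(peak))))
    return out


def detect_cis(
    insertions: pd.DataFrame,
    chrom_sizes: dict[str, int],
    scales=DEFAULT_SCALES,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[CISRegion]:
    """Detect common insertion sites across chromosomes and kernel scales.

    Insertions are pooled across tumors and orientations; per-tumor
    multiplicity is retained (a tumor with three insertions contributes
    three kernels). Overlapping regions from different scales merge into a
    single CIS spanning their union, reported at the smallest contributing
    scale. n_tumors counts distinct tumors with an insertion inside
    [start, end]. Deterministic given ``seed``; invariant to input order.
    """
    if not scales:
        raise ValueError("at least one kernel scale is required")
    regions: list[CISRegion] = []
    if insertions.empty:
        return regions
    threshold_cache = _THRESHOLD_CACHE
    for chrom, sub in insertions.groupby("chrom", sort=True):
        length = chrom_sizes[chrom]
        positions = np.sort(sub["position"].to_numpy(dtype=float))
        n = len(positions)
        per_scale: list[tuple[int, int, int, float, float]] = []
        for scale in sorted(scales, key=lambda s: s.h):
            key = (n, length, scale.h, scale.grid_step, alpha, n_perm, seed)
            if key not in threshold_cache:
                child_seed = [seed, n % (2**31), int(scale.h) % (2**31)]
                threshold_cache[key] = null_peak_threshold(
                    n, length, scale, alpha=alpha, n_perm=n_perm, seed=child_seed
                )
            thr = threshold_cache[key]
            track = kernel_density(positions, scale, length, chrom=chrom)
            for start, end, peak in _regions_above(track, thr):
                per_scale.append((start, end, peak, scale.h, thr))
        merged = _merge_regions(per_scale)
        for start, end, peak, h, thr in merged:
            inside = sub[(sub["position"] >= start) & (sub["position"] <= end)]
            regions.append(
                CISRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    peak=peak,
                    scale=h,
                    n_insertions=len(inside),
                    n_tumors=inside["tumor_id"].nunique(),
                    threshold=thr,
                )
            )
    return regions


def _merge_regions(per_scale):
    """Merge overlapping (start, end) intervals from different scales.

    The merged record keeps the peak and threshold of the smallest
    contributing scale (ties toward the smaller start coordinate).
    """
    if not per_scale:
        return []
    items = sorted(per_scale, key=lambda r: (r[0], r[1]))
    merged = []
    cur = list(items[0])
    members = [items[0]]
    for rec in items[1:]:
        if rec[0] <= cur[1]:  # 1-based inclusive overlap
            cur[1] = max(cur[1], rec[1])
            members.append(rec)
        else:
            merged.append(_finalize_merge(cur, members))
            cur = list(rec)
            members = [rec]
    merged.append(_finalize_merge(cur, members))
    return merged


def _finalize_merge(cur, members):
    best = min(members, key=lambda r: (r[3], r[0]))
    return (cur[0], cur[1], best[2], best[3], best[4])


def assign_targets(
    cis_list: list[CISRegion], annotation: pd.DataFrame
) -> list[CISRegion]:
    """Annotate each CIS with a candidate target gene (nearest-gene heuristic).

    The target is the gene overlapping the CIS peak, otherwise the gene
    nearest to it; on an exact distance tie the upstream gene (smaller
    coordinate, i.e. upstream relative to the + strand) wins. This is an
    automated heuristic, not curation. An empty annotation leaves targets
    unset.
    """
    out = []
    for cis in cis_list:
        genes = annotation[annotation["chrom"] == cis.chrom]
        if genes.empty:
            out.append(replace(cis, target=None))
            continue
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        dist = np.where(
            (cis.peak >= start) & (cis.peak <= end),
            0,
            np.minimum(np.abs(start - cis.peak), np.abs(end - cis.peak)),
        )
        best = np.lexsort((start, dist))[0]
        out.append(replace(cis, target=str(genes.iloc[best]["name"])))
    return out


def cis_table(cis_list: list[CISRegion]) -> pd.DataFrame:
    """BED-like summary table of detected CISs."""
    rows = [
        (
            c.chrom,
            c.start,
            c.end,
            c.target or c.cis_id,
            c.n_tumors,
            c.peak,
            c.scale,
            c.threshold,
            c.n_insertions,
        )
        for c in cis_list
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "name",
            "score",
            "peak",
            "scale",
            "threshold",
            "n_insertions",
        ],
    )


def _in_any_cis(insertions: pd.DataFrame, cis_list: list[CISRegion]) -> pd.Series:
    mask = pd.Series(False, index=insertions.index)
    for cis in cis_list:
        mask |= (
            (insertions["chrom"] == cis.chrom)
            & (insertions["position"] >= cis.start)
            & (insertions["position"] <= cis.end)
        )
    return mask


def tumors_in_cis_fraction(
    insertions: pd.DataFrame, cis_list: list[CISRegion], tumors: pd.DataFrame
) -> pd.DataFrame:
    """Per-stratum fraction of tumors contributing an insertion to any CIS.

    The denominator is the post-filter tumor set (tumors that retained at
    least one insertion); percentages use standard rounding.
    """
    in_cis = _in_any_cis(insertions, cis_list)
    tumors_with_cis = set(insertions.loc[in_cis, "tumor_id"])
    retained = set(insertions["tumor_id"])
    rows = []
    for (strain, genotype), grp in tumors.groupby(["strain", "genotype"], sort=True):
        ids = [t for t in grp["tumor_id"] if t in retained]
        n_hit = sum(t in tumors_with_cis for t in ids)
        pct = round(100.0 * n_hit / len(ids)) if ids else None
        rows.append((strain, genotype, len(ids), n_hit, pct))
    return pd.DataFrame(
        rows, columns=["strain", "genotype", "n_tumors", "n_with_cis", "pct_with_cis"]
    )


def fraction_insertions_in_cis(
    insertions: pd.DataFrame, cis_list: list[CISRegion]
) -> tuple[int, int, float]:
    """(n inside a CIS, n total, percent to one decimal place)."""
    n_total = len(insertions)
    n_in = int(_in_any_cis(insertions, cis_list).sum())
    pct = round(100.0 * n_in / n_total, 1) if n_total else float("nan")
    return n_in, n_total, pct


def known_site_overlap(
    cis_list: list[CISRegion], known: pd.DataFrame
) -> tuple[int, int, int]:
    """Compare detected CISs against a list of previously reported sites.

    ``known`` has columns chrom, start, end (1-based inclusive). Returns
    (n confirmed, n known, integer percent of known sites NOT confirmed).
    """
    confirmed = 0
    for _, row in known.iterrows():
        hit = any(
            c.chrom == row["chrom"] and c.start <= row["end"] and c.end >= row["start"]
            for c in cis_list
        )
        confirmed += bool(hit)
    n_known = len(known)
    pct_not = round(100.0 * (1.0 - confirmed / n_known)) if n_known else 0
    return confirmed, n_known, pct_not
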