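# Methods

## The measurement model

A shear/splinkerette screen reads each proviral insertion out as a set of
junction fragments. All fragments of one insertion share the junction
coordinate (the viral 5′ end in the host genome) but differ in where the
tumor DNA was sheared before adapter ligation. Because shearing is random
per cell, two fragments with the same **ligation point (LP)** are PCR/optical
copies of one molecule, while distinct LPs mark independent cells. An
insertion with *n* distinct LPs was therefore present in at least *n* cells,
and within one tumor the LP count ranks insertions by clonality: high-LP
insertions arose early (or were strongly selected), low-LP insertions late.
LP counts are never compared across tumors — sequencing depth differs per
tumor, so clonality is strictly a relative, within-tumor quantity.

## Insertion calling

Fragments from the same tumor, chromosome and orientation whose junction
positions differ by ≤ `merge_window` (default 5 bp, absorbing alignment
slip; junctions are nominally exact) are clustered into one insertion.
Orientation is part of the clustering key because sense and antisense
insertions at one locus are distinct biological events. The representative
position is the modal junction coordinate (ties → smallest); `lp_count` is
the number of distinct ligation points, `read_count` the cluster size, so
read counts sum exactly to the fragment count (conservation, tested).

The **single-LP filter** keeps insertions with `lp_count ≥ 2`. A single-LP
insertion is indistinguishable from an integration present in one cell and
is overwhelmingly background. Tumors that lose every insertion are flagged
in the run report and excluded from downstream denominators. Integer
percentages for the reported reductions are **floored**, so a printed
reduction is never overstated.

An optional cross-contamination filter (off by default) handles barcode
bleed in pooled runs: an identical (chrom, position, ligation point) triple
seen in several tumors of one pool is kept only in the tumor with the most
supporting fragments. This is a standard pooled-sequencing control, built
here as an extension; the main chain does not depend on it.

## CIS detection by Gaussian kernel convolution

Insertion positions are pooled across tumors and orientations, keeping
per-tumor multiplicity (a tumor with three insertions contributes three
kernels; collapsing duplicates is configurable upstream by deduplicating
the input). The smoothed intensity at grid point *g* is

    f(g) = Σᵢ exp(−(g − xᵢ)² / (2h²))

with the kernel unnormalized so an isolated insertion contributes exactly
1.0 at its own coordinate and k coincident insertions a peak of exactly k.
Contributions are truncated beyond 4h (omitted tail mass ≈ 6·10⁻⁵ per
kernel); the evaluation grid is anchored at coordinate 1 with spacing h/10,
which resolves peak locations to within 5 % of h.

**Significance.** For each chromosome and scale, the null distribution of
the maximum peak is obtained by placing the same number of insertions
uniformly on the chromosome `n_perm` times (default 1000); the empirical
(1 − α) quantile (default α = 0.05) is the calling threshold. This controls
the family-wise error rate per chromosome/scale and makes no distributional
assumptions. The null maximum is evaluated both on the grid and at the
exact permuted coordinates, so the single-insertion null is exactly 1.0;
observed tracks are evaluated on the grid, which is (negligibly, ≤ 0.15 %)
conservative. Thresholds are memoized on (n, length, scale, α, n_perm,
seed) — they are pure functions of that key.

Contiguous grid runs above threshold become regions; regions from different
scales that overlap are merged into one CIS spanning their union, reported
at the smallest contributing scale (small scales localize, large scales
catch dispersed patterns — the default 10/30/100 kb ladder covers the
~15–270 kb range of empirically reported CIS widths). Per-CIS tumor counts
are distinct tumors with an insertion inside [start, end].

Target genes are annotated with a **nearest-gene heuristic** (gene
overlapping the peak, else nearest by distance, ties → upstream gene) and
recorded as such — automated assignment stands in for manual curation and
is never presented as curation.

## Association testing

Presence of a CIS in a tumor means a clonality score (max LP count of that
tumor's insertions in the CIS) of ≥ 2, matching the filter floor. For a
pair of CISs the 2×2 table of presence is tested with both one-sided exact
hypergeometric tails: enrichment of the overlap (co-occurrence) and
depletion (mutual exclusivity). The reported direction is the smaller tail;
both p-values are retained, and the identity p_enrich + p_deplete ≥ 1 holds
at every table (both tails contain the observed table). Degenerate margins
(CIS in no or every tumor) are excluded before correction so they do not
dilute the Benjamini–Hochberg denominator; BH is applied across the pooled
set of both one-sided families, controlling the FDR of displayed edges as a
whole. One-sided exact testing has an intrinsic power asymmetry —
co-occurrence of rare CISs reaches significance quickly, exclusivity needs
frequent CISs — which is visible in the synthetic cohorts as exclusivity
edges concentrating among the high-frequency loci.

Family-level exclusivity uses a permutation null that shuffles each
member's presence column independently (margins preserved; 1000
permutations, seeded) and asks whether the number of tumors hitting ≥ 2
members is lower than expected. Genotype/strain association compares
matched cohorts only (wild type vs engineered model within a strain;
wild-type strains against each other) with two-sided exact tests and BH
across CISs.

## Progression ordering

CISs are pooled into gene families via the target-gene map; unassigned
CISs become singleton groups; groups present in fewer than `min_tumors`
(default 10) tumors are dropped. A tumor's group score is the **maximum** LP
count over member CISs — within-family exclusivity makes multi-member hits
rare, so max is the natural representative (sum is available via the
incidence matrix if wanted). For each group pair, tumors carrying both
groups are split into wins for either side; ties are excluded (standard
sign-test practice). The p-value is the exact binomial
2·min(P(X ≥ w), P(X ≤ w)) at p = ½, capped at 1 — two-sided by default
since directionality is read off post hoc; a one-sided mode exists.
Comparisons with p ≤ 0.05 become directed edges from the group with more
wins; following the convention of reporting each pairwise relation at
P < 0.05, no multiple-testing correction is applied by default (a BH option
exists). Acyclicity of the resulting graph is checked and reported, not
enforced.

## The synthetic cohort generator

The generator emulates the screen the pipeline is built for, and its
defaults are the package's study conditions:

- **Genome**: 5 chromosomes × 400 Mb. Chromosome count is reduced for
  clarity, but total length (2 Gb) is chosen so per-bp background insertion
  density matches a mouse-genome-scale screen with ~6.6 k retained
  insertions — detectability of rare loci depends on that density.
- **Loci**: 30 planted driver loci in five families (Wnt, Fgf/Egf, Fgfr,
  Rspo, Pdgfr) plus 13 singletons. Per-tumor hit probabilities follow the
  per-locus tumor counts of large published screens (top locus 45 %,
  i.e. 270/600), floored at 20 expected insertions per locus (p = 0.0333)
  so every planted locus is recoverable at cohort scale; placement spread
  per locus is ~1/6 of the empirical CIS widths (3–35 kb).
- **Events**: each locus is hit independently with its probability; with
  exclusivity on (default), at most one member per family survives per
  tumor (weighted choice). Hit groups are ranked by the planted temporal
  order (Wnt, Fgf earliest); the clonal fraction of rank r halves per step
  (1, ½, ¼, …), and LP counts are drawn as 1 + Poisson(lp_depth·cf − 1)
  with lp_depth = 40 — every insertion keeps ≥ 1 fragment and the mean is
  monotone in clonal fraction. The expected events per tumor (~2) is a
  consequence of the locus probabilities, not an independent dial.
- **Background**: Poisson(49) insertions per tumor, uniform over the
  genome, LP ~ Geometric(p = 0.8) so 80 % are single-LP. Together with ~2
  planted events this yields ~51 pre-filter insertions per tumor and a
  post-filter cohort of ~6.9 k insertions of which ~17 % lie in CISs —
  the regime of a real 600-tumor screen.
- **Fragments**: an insertion with k LPs emits k distinct shear offsets
  drawn without replacement from 100–1000 bp on the side opposite the
  viral junction, each with 1 + Poisson(0.5) duplicate reads. All
  randomness flows from one generator seeded by `SimConfig.seed`; equal
  seeds give byte-identical fragment tables.

**What the generator does not model** — and hence what green tests do not
certify about real data: mappability gaps and alignment error, integration
sequence bias, chromatin-driven hotspots, copy-number alteration of LP
counts, inter-tumor contamination (beyond the optional filter's test
fixture), multiple independent tumors per sample, and genotype-specific
insertion biology (none is planted, matching a negative-control design).
The LP-count distributions (Poisson for events, geometric for background)
are modeling choices, not measured distributions; both are configurable.

## Numerical and design notes

- Coordinates are 1-based inclusive throughout; BED exports convert to
  0-based half-open.
- Modal-position ties and peak ties break toward the smaller coordinate;
  equidistant gene assignment breaks toward the upstream gene.
- Percentages: reductions are floored integers (never overstated);
  fractions of insertions in CISs are rounded to one decimal; stratum
  percentages to integers.
- The permutation threshold uses the `higher` empirical quantile, which is
  conservative at finite n_perm.
- Validation problem sizes: the replicate recovery study uses 20 cohorts of
  600 tumors at n_perm = 200 (threshold Monte-Carlo error at the 95th
  percentile is small relative to the planted signal-to-threshold margin);
  single-cohort runs default to n_perm = 1000.
- Known limitations: the caller assumes junction coordinates are exact up
  to a few bp and cannot separate two same-orientation insertions closer
  than `merge_window`; CIS boundaries are grid-quantized (h/10); the sign
  test ignores the magnitude of clonality differences; and the progression
  graph is a summary of pairwise relations, not a joint model of tumor
  phylogenies.
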