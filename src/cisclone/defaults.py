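"""Default synthetic-cohort configuration.

Emulates a ~600-tumor mammary-tumor screen: 30 planted driver loci drawn
from five mutually exclusive gene families (Wnt, Fgf/Egf, Fgfr, Rspo,
Pdgfr) plus singleton loci, on a 5 x 400 Mb genome, with a heavy
mostly-single-LP background load. Locus hit frequencies follow the
empirical per-locus tumor counts of large MMTV screens (most frequent
locus ~45% of tumors), floored at 20 expected insertions per locus so
every planted locus is recoverable at cohort scale. The planted temporal
order places Wnt and Fgf events earliest; receptor and other families are
later events with proportionally lower clonal fractions.
"""

from __future__ import annotations

from .simulate import CISLocusSpec, GenomeLayout, SimConfig

DEFAULT_GENOME = GenomeLayout(
    names=("chr1", "chr2", "chr3", "chr4", "chr5"),
    lengths=(400_000_000,) * 5,
)

# name, family/group, chrom, center, spread (bp), per-tumor hit probability
_LOCI = [
    ("Wnt1", "Wnt", "chr1", 50_000_000, 30_000, 0.450),
    ("Wnt3a", "Wnt", "chr1", 120_000_000, 25_000, 0.140),
    ("Fgf3", "Fgf", "chr1", 200_000_000, 30_000, 0.325),
    ("Map3k8", "Map3k8", "chr1", 290_000_000, 15_000, 0.050),
    ("Metrnl", "Metrnl", "chr1", 360_000_000, 8_000, 0.0333),
    ("Chl1", "Chl1", "chr2", 30_000_000, 6_000, 0.0333),
    ("Wnt3", "Wnt", "chr2", 60_000_000, 28_000, 0.100),
    ("Fgf8", "Fgf", "chr2", 150_000_000, 33_000, 0.225),
    ("Notch2", "Notch2", "chr2", 200_000_000, 5_000, 0.0333),
    ("Fgfr2", "Fgfr", "chr2", 250_000_000, 35_000, 0.085),
    ("Irs4", "Irs4", "chr2", 320_000_000, 20_000, 0.0383),
    ("Fgf10", "Fgf", "chr3", 40_000_000, 5_000, 0.0333),
    ("Fgf6", "Fgf", "chr3", 90_000_000, 3_000, 0.0333),
    ("Fgfr1", "Fgfr", "chr3", 150_000_000, 35_000, 0.050),
    ("Sfi1", "Sfi1", "chr3", 200_000_000, 3_000, 0.0333),
    ("Igf2", "Igf2", "chr3", 250_000_000, 15_000, 0.0333),
    ("Sfmbt2", "Sfmbt2", "chr3", 320_000_000, 14_000, 0.0333),
    ("Hbegf", "Fgf", "chr4", 30_000_000, 12_000, 0.0333),
    ("Fgfr3", "Fgfr", "chr4", 90_000_000, 4_000, 0.0333),
    ("Rspo2", "Rspo", "chr4", 150_000_000, 25_000, 0.080),
    ("Rspo3", "Rspo", "chr4", 250_000_000, 20_000, 0.0417),
    ("Rspo3_enh", "Rspo", "chr4", 251_500_000, 6_000, 0.0333),
    ("Dock5", "Dock5", "chr4", 330_000_000, 4_000, 0.0333),
    ("Fezf1", "Fezf1", "chr4", 370_000_000, 4_500, 0.0333),
    ("Rspo1", "Rspo", "chr5", 40_000_000, 6_000, 0.0333),
    ("Pdgfra", "Pdgfr", "chr5", 100_000_000, 12_000, 0.0333),
    ("Pdgfrb", "Pdgfr", "chr5", 160_000_000, 8_000, 0.0333),
    ("Reg_feat", "Reg_feat", "chr5", 200_000_000, 5_000, 0.0333),
    ("Eras", "Eras", "chr5", 250_000_000, 11_000, 0.0333),
    ("Myb", "Myb", "chr5", 320_000_000, 10_000, 0.0333),
]

DEFAULT_LOCI = tuple(
    CISLocusSpec(name=n, group=g, chrom=c, center=pos, spread=sp, hit_probability=p)
    for n, g, c, pos, sp, p in _LOCI
)

#: planted temporal order, earliest first: ligand families initiate, the
#: receptor and accessory families are progression events
DEFAULT_GROUP_ORDER = (
    "Wnt",
    "Fgf",
    "Fgfr",
    "Rspo",
    "Pdgfr",
    "Map3k8",
    "Irs4",
    "Igf2",
    "Sfmbt2",
    "Eras",
    "Myb",
    "Metrnl",
    "Chl1",
    "Notch2",
    "Sfi1",
    "Dock5",
    "Fezf1",
    "Reg_feat",
)

#: four cohorts: two wild-type strains and their engineered counterparts,
#: with proportions matching a 604-tumor screen (80/59/265/200)
DEFAULT_STRATA = (
    ("BALB/c", "wt", 80 / 604),
    ("BALB/c", "K14Cre;Trp53F/F", 59 / 604),
    ("FVB", "wt", 265 / 604),
    ("FVB", "Pten+/-", 200 / 604),
)

#: gene-family membership used for grouping detected CISs
DEFAULT_FAMILIES = {
    "Wnt": ["Wnt1", "Wnt3a", "Wnt3"],
    "Fgf": ["Fgf3", "Fgf8", "Fgf6", "Fgf10", "Hbegf"],
    "Fgfr": ["Fgfr1", "Fgfr2", "Fgfr3"],
    "Rspo": ["Rspo1", "Rspo2", "Rspo3", "Rspo3_enh"],
    "Pdgfr": ["Pdgfra", "Pdgfrb"],
}


def default_config(n_tumors: int = 600, seed: int = 0, **overrides) -> SimConfig:
    """The default study conditions; ``overrides`` replace SimConfig fields."""
    kwargs = dict(
        genome=DEFAULT_GENOME,
        loci=DEFAULT_LOCI,
        group_order=DEFAULT_GROUP_ORDER,
        n_tumors=n_tumors,
        strata=DEFAULT_STRATA,
        background_rate=49.0,
        lp_depth=40.0,
        exclusivity=True,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
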