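"""End-to-end orchestration: simulate -> call -> filter -> CIS -> network -> progression.

Every stage writes its artifact under the output directory in the package's
own text formats, so any intermediate can be re-read and re-run separately.
The run report is a JSON document with the counts a screen analyst checks
first: insertions before/after the LP filter with percent reductions,
number of CISs, per-stratum fraction of tumors contributing to a CIS, and
the sizes of the association network and progression graph, plus full
provenance (config, seed, package version).
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, calling, cis as cis_mod, io, network, progression
from .defaults import DEFAULT_FAMILIES, default_config
from .simulate import SimConfig, SimTruth, simulate_cohort


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    out_dir: str = "results"
    fragments: str | None = None  # None -> simulate a cohort
    tumors: str | None = None
    chrom_sizes: str | None = None
    annotation: str | None = None
    n_tumors: int = 600  # simulated cohort size when no fragments are given
    merge_window: int = 5
    min_lp: int = 2
    scales_bp: tuple[float, ...] = (10_000.0, 30_000.0, 100_000.0)
    alpha_cis: float = 0.05
    n_perm: int = 1000
    alpha_network: float = 0.05
    alpha_progression: float = 0.05
    min_group_tumors: int = 10
    families: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_FAMILIES.items()})
    cross_contamination_filter: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config fields: {sorted(unknown)}")
        if "scales_bp" in raw:
            raw["scales_bp"] = tuple(float(x) for x in raw["scales_bp"])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales_bp"] = list(self.scales_bp)
        return d


def _require(config: RunConfig, name: str) -> Path:
    value = getattr(config, name)
    if value is None:
        raise PipelineError("inputs", f"config field '{name}' is required but not set")
    path = Path(value)
    if not path.exists():
        raise PipelineError("inputs", f"config field '{name}': no such file {path}")
    return path


def run_pipeline(config: RunConfig, sim_config: SimConfig | None = None) -> dict:
    """Execute all stages; returns the report dict (also written to report.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.as_dict(),
        "seed": config.seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    truth: SimTruth | None = None

    # --- inputs: simulate or load ---
    if config.fragments is None:
        sim = sim_config or default_config(n_tumors=config.n_tumors, seed=config.seed)
        fragments, truth = simulate_cohort(sim)
        tumors = truth.tumors
        chrom_sizes = sim.genome.sizes
        io.write_fragments(fragments, out / "fragments.tsv")
        io.write_tumor_table(tumors, out / "tumors.tsv")
        io.write_chrom_sizes(sim.genome.names, sim.genome.lengths, out / "chrom.sizes")
        truth.to_json(out / "truth.json")
        report["stages"]["simulate"] = {
            "n_tumors": int(len(tumors)),
            "n_fragments": int(len(fragments)),
            "n_planted_events": int(len(truth.events)),
            "n_background_insertions": int(truth.n_background),
        }
    else:
        fragments = io.read_fragments(_require(config, "fragments"))
        tumors = io.read_tumor_table(_require(config, "tumors"))
        chrom_sizes = io.read_chrom_sizes(_require(config, "chrom_sizes"))

    # --- insertion calling and LP filter ---
    try:
        if config.cross_contamination_filter:
            fragments = calling.cross_contamination_filter(fragments)
        raw = calling.call_insertions(fragments, merge_window=config.merge_window)
        io.write_insertions(raw, out / "insertions_unfiltered.tsv")
        filt = calling.filter_single_lp(raw, min_lp=config.min_lp)
        insertions = filt.insertions
        io.write_insertions(insertions, out / "insertions.tsv")
        summary = calling.cohort_summary(insertions, raw)
        report["stages"]["call_and_filter"] = {
            **summary.as_dict(),
            "tumors_dropped_by_filter": filt.dropped_tumors,
        }
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("call_and_filter", str(exc)) from exc

    # --- CIS detection ---
    try:
        scales = tuple(cis_mod.KernelScale(h) for h in config.scales_bp)
        cis_list = cis_mod.detect_cis(
            insertions,
            chrom_sizes,
            scales=scales,
            alpha=config.alpha_cis,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        annotation = None
        if config.annotation is not None:
            annotation = io.read_gene_annotation(_require(config, "annotation"))
        elif truth is not None:
            annotation = _truth_annotation(truth)
        if annotation is not None:
            cis_list = cis_mod.assign_targets(cis_list, annotation)
        cis_mod.cis_table(cis_list).to_csv(out / "cis.tsv", sep="\t", index=False)
        strata = cis_mod.tumors_in_cis_fraction(insertions, cis_list, tumors)
        n_in, n_total, pct_in = cis_mod.fraction_insertions_in_cis(insertions, cis_list)
        report["stages"]["cis"] = {
            "n_cis": len(cis_list),
            "n_insertions_in_cis": n_in,
            "pct_insertions_in_cis": pct_in,
            "tumors_in_cis_by_stratum": strata.to_dict(orient="records"),
        }
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("cis", str(exc)) from exc

    # --- association network ---
    try:
        matrix = network.build_incidence(insertions, cis_list, tumors)
        matrix.to_csv(out / "incidence.tsv", sep="\t")
        edges = []
        if len(matrix.columns) >= 2:
            edges = network.build_network(matrix, alpha=config.alpha_network)
            network.edges_table(edges).to_csv(out / "network_edges.tsv", sep="\t", index=False)
            network.edges_to_graphml(edges, out / "network.graphml")
        report["stages"]["network"] = {
            "n_edges": len(edges),
            "n_cooccurring": sum(e.direction == "co-occurring" for e in edges),
            "n_mutually_exclusive": sum(e.direction == "mutually-exclusive" for e in edges),
        }
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("network", str(exc)) from exc

    # --- progression ordering ---
    try:
        family_map = _family_map_for_cis(cis_list, config.families)
        groups = progression.group_cis(matrix, family_map, min_tumors=config.min_group_tumors)
        scores = progression.group_scores(matrix, groups)
        comparisons = progression.all_comparisons(scores)
        progression.comparisons_table(comparisons).to_csv(
            out / "clonality_comparisons.tsv", sep="\t", index=False
        )
        prog_edges, acyclic = progression.progression_graph(
            comparisons, alpha=config.alpha_progression
        )
        progression.edges_table(prog_edges).to_csv(
            out / "progression_edges.tsv", sep="\t", index=False
        )
        progression.edges_to_graphml(prog_edges, out / "progression.graphml")
        report["stages"]["progression"] = {
            "n_groups": len(groups),
            "n_comparisons": len(comparisons),
            "n_edges": len(prog_edges),
            "acyclic": bool(acyclic),
        }
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("progression", str(exc)) from exc

    io.write_json(report, out / "report.json")
    return report


def _truth_annotation(truth: SimTruth) -> pd.DataFrame:
    """Gene-like annotation intervals derived from the planted loci."""
    rows = [
        (l.chrom, *l.interval, "+", l.name) for l in truth.loci
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])


def _family_map_for_cis(cis_list, families: dict) -> dict[str, list[str]]:
    """Translate gene-level family membership into CIS-id membership via targets."""
    gene_to_family = {}
    for fam, genes in families.items():
        for g in genes:
            gene_to_family[g] = fam
    family_map: dict[str, list[str]] = {}
    for c in cis_list:
        fam = gene_to_family.get(c.target) if c.target else None
        if fam is not None:
            family_map.setdefault(fam, []).append(c.cis_id)
    return family_map
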