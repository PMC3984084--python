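"""End-to-end orchestration of the collapsed-duplication analysis.

A run takes a scenario directory (or generates one from a seed), then walks
the stages in dependency order: outward-primer PCR diagnosis, clone
assembly, collapse detection, paralog comparison (catalog, protein, trio),
restriction-digest clone typing, segregation analysis, and the read-depth
duplication scan. Each stage writes its own artifacts; a consolidated JSON
report collects every headline number with a provenance block. Reruns with
the same config and seed reproduce the identical report (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import assembly as asm
from . import compare as cmp
from . import coverage as cov
from . import digest as dig
from . import pcr
from . import segregation as seg
from . import synthetic as syn
from .seqio import read_tsv, write_fasta, write_tsv

log = logging.getLogger("tandemscan")

ALL_STAGES = ("pcr", "assembly", "collapse", "compare", "digest",
              "segregation", "coverage")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "tandemscan_run"
    scenario_dir: str | None = None      # None: generate a scenario from seed
    stages: tuple[str, ...] = ALL_STAGES
    intergenic_len: int = 1511
    collapse_len: int = 7000
    flank_len: int = 12000
    max_product_len: int = 6000
    min_overlap: int = 100
    anchor_len: int = 50
    enzyme: str = "BpiI"
    read_len: int = 100
    read_depth: float = 30.0
    map_max_edits: int = 20
    cov_window: int = 100
    cov_threshold: float = 1.75
    cov_min_windows: int = 3
    offspring_n: int = 120

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        data.pop("outdir", None)    # a location, not an analysis parameter
        return hashlib.sha256(json.dumps(data, sort_keys=True).encode()).hexdigest()[:16]

    def log_non_defaults(self) -> None:
        default = RunConfig()
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v != getattr(default, f.name):
                log.info("config %s = %r (non-default)", f.name, v)


@dataclass
class AnalysisReport:
    stages: dict[str, dict] = field(default_factory=dict)
    failed: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failed

    def to_dict(self) -> dict:
        return {"stages": self.stages, "failed": self.failed,
                "skipped": self.skipped, "provenance": self.provenance}


# stage dependencies: a stage is skipped when a prerequisite failed
_DEPS = {"collapse": ("assembly",)}


def run_pipeline(config: RunConfig) -> AnalysisReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.log_non_defaults()
    report = AnalysisReport()
    report.provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    scenario = syn.generate_scenario(
        intergenic_len=config.intergenic_len, seed=config.seed,
        collapse_len=config.collapse_len, flank_len=config.flank_len)
    if config.scenario_dir is None:
        syn.write_scenario(scenario, outdir / "scenario",
                           reads_depth=config.read_depth, read_len=config.read_len,
                           offspring_n=config.offspring_n)
        scen_dir = outdir / "scenario"
    else:
        scen_dir = Path(config.scenario_dir)
        if not scen_dir.is_dir():
            raise FileNotFoundError(f"scenario directory {scen_dir} not found")

    state: dict[str, object] = {}
    runners = {
        "pcr": _stage_pcr,
        "assembly": _stage_assembly,
        "collapse": _stage_collapse,
        "compare": _stage_compare,
        "digest": _stage_digest,
        "segregation": _stage_segregation,
        "coverage": _stage_coverage,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if any(d in report.failed or d in report.skipped for d in _DEPS.get(stage, ())):
            log.warning("stage %s skipped: prerequisite failed", stage)
            report.skipped.append(stage)
            continue
        try:
            report.stages[stage] = runners[stage](config, scenario, scen_dir,
                                                 outdir, state)
        except Exception as err:   # stage isolation is the contract here
            log.error("stage %s failed: %s", stage, err)
            report.failed.append(stage)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, default=str)
    return report


def _stage_pcr(config, scenario, scen_dir, outdir, state):
    pa = pcr.Primer("A", scenario.primers["A"])
    pb = pcr.Primer("B", scenario.primers["B"])
    evidence = {}
    products = {}
    for name, prs in (("A", [pa]), ("B", [pb]), ("A+B", [pa, pb])):
        res = pcr.predict_products(prs, scenario.true_locus, config.max_product_len)
        evidence[name] = res.has_product
        products[name] = [a.length for a in res.amplicons]
    call = pcr.classify_arrangement(evidence)
    return {"evidence": evidence, "product_lengths": products,
            "arrangement": call.arrangement}


def _stage_assembly(config, scenario, scen_dir, outdir, state):
    frags = asm.tile_fragments(scenario.true_locus, 4, 3 * config.min_overlap,
                               labels=["a-I", "a-II", "b-I", "b-II"])
    layout = asm.assemble_overlaps(frags, min_overlap=config.min_overlap)
    state["contig"] = layout.contig
    write_fasta(outdir / "assembled_locus.fasta", {"assembled": layout.contig})
    return {"n_fragments": len(frags), "contig_len": len(layout.contig),
            "order": layout.order,
            "identical_to_truth": layout.contig == scenario.true_locus}


def _stage_collapse(config, scenario, scen_dir, outdir, state):
    contig = state.get("contig", scenario.true_locus)
    rep = asm.detect_collapsed_segment(str(contig), scenario.collapsed_reference,
                                       anchor_len=config.anchor_len)
    return rep.to_dict()


def _stage_compare(config, scenario, scen_dir, outdir, state):
    aln = cmp.align_pair(scenario.unit_a, scenario.unit_b)
    cat = cmp.catalog_diffs(aln, scenario.unit_features_a)
    pdiff = cmp.protein_diff(scenario.cds_a, scenario.cds_b)
    trio = cmp.trio_analysis(scenario.unit_a, scenario.unit_b, scenario.outgroup_gene)
    per_feat = [dataclasses.asdict(f) for f in cat.per_feature]
    write_tsv(outdir / "feature_identity.tsv",
              __import__("pandas").DataFrame(per_feat))
    return {
        "summary": cat.summary(),
        "protein_tokens": pdiff.tokens,
        "protein_indels": [dataclasses.asdict(i) for i in pdiff.indels],
        "trio": {"identities": trio.pairwise_identities, "topology": trio.topology,
                 "polarity_counts": _count(trio.indel_polarity.values())},
    }


def _stage_digest(config, scenario, scen_dir, outdir, state):
    enz = dig.ENZYMES[config.enzyme]
    pat_a = dig.digest(scenario.cds_a, enz, "cds_a")
    pat_b = dig.digest(scenario.cds_b, enz, "cds_b")
    refs = {"a": pat_a, "b": pat_b}
    clones = {"clone_1": scenario.cds_a, "clone_2": scenario.cds_b,
              "clone_3": scenario.cds_b}
    typed = {name: dig.classify_by_pattern(dig.digest(s, enz, name), refs)
             for name, s in clones.items()}
    return {"cuts_a": pat_a.cut_positions, "cuts_b": pat_b.cut_positions,
            "fragments_a": pat_a.fragment_lengths,
            "fragments_b": pat_b.fragment_lengths, "clone_calls": typed}


def _stage_segregation(config, scenario, scen_dir, outdir, state):
    rows = []
    table = read_tsv(scen_dir / "offspring.tsv")
    for _, row in table.iterrows():
        counts = seg.GenotypeCounts(int(row.n_ww), int(row.n_wm), int(row.n_mm))
        res = seg.chisq_gof(counts)
        best = seg.select_hypothesis(counts).best
        rows.append({"line": row.line, "n_ww": counts.n_ww, "n_wm": counts.n_wm,
                     "n_mm": counts.n_mm, "chi2": round(res.chi2, 3), "df": res.df,
                     "p": round(res.p, 3), "verdict": res.verdict, "best_model": best})
    write_tsv(outdir / "segregation.tsv", __import__("pandas").DataFrame(rows))
    return {"lines": rows}


def _stage_coverage(config, scenario, scen_dir, outdir, state):
    reads = syn.simulate_reads(scenario.true_locus, config.read_len,
                               config.read_depth, seed=config.seed + 1)
    depth = cov.map_reads(reads, scenario.collapsed_reference,
                          max_edits=config.map_max_edits)
    prof, calls = cov.scan_duplications(depth, config.cov_window,
                                        config.cov_threshold, config.cov_min_windows)
    bed = [(f"collapsed_ref\t{c.interval[0]}\t{c.interval[1]}\t"
            f"dup_ratio_{c.mean_ratio:.2f}") for c in calls]
    (outdir / "duplication_calls.bed").write_text("\n".join(bed) + ("\n" if bed else ""))
    s, e = scenario.truth["inserted_interval_locus"]
    dup_ref = (config.flank_len, scenario.truth["breakpoint_reference"])
    hit = any(c.interval[0] < dup_ref[1] and c.interval[1] > dup_ref[0] for c in calls)
    return {"window": config.cov_window, "threshold": config.cov_threshold,
            "genome_median": prof.genome_median,
            "n_calls": len(calls),
            "calls": [{"interval": list(c.interval), "mean_ratio": round(c.mean_ratio, 3),
                       "n_windows": c.n_windows} for c in calls],
            "truth_region_hit": hit}


def _count(values) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return out
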