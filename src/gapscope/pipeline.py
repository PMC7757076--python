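"""Stage orchestration and run manifests.

Stages run in dependency order; a failing stage halts its dependents while
independent stages continue. Every TSV/BED written by a stage carries a
'#'-prefixed provenance header (tool version, config hash, inputs), and the
manifest records a digest for every output so deterministic reruns are
byte-checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .config import AnalysisConfig
from .assembly_metrics import assembly_summary, missing_fraction
from .base_composition import find_g4_motifs, g4_summary, gc_windows
from .gap_cause import run_gap_analysis, tabulate_gap_causes
from .genome_io import read_fasta, write_bed, write_fasta
from .homology_census import ExonQuerySet, exon_census, gene_presence
from .sex_linkage import CoverageTable, classify_sex_linkage, flag_chimeric_scaffolds
from .synthetic_data import (
    SimulationConfig,
    build_truth_genome,
    derive_draft,
    simulate_coverage_table,
)

log = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "stats", "gapcause", "gc", "g4", "census", "genes", "sexlink"]
#: stages that consume the simulator's outputs when no explicit inputs are given
_NEEDS_DATA = {"stats", "gapcause", "gc", "g4", "census", "genes", "sexlink"}


@dataclass
class StageStatus:
    name: str
    status: str  # completed | failed | skipped
    outputs: list[str] = field(default_factory=list)
    error: str | None = None


@dataclass
class RunManifest:
    config_hash: str
    tool_version: str
    stages: list[StageStatus] = field(default_factory=list)
    output_digests: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return any(s.status == "failed" for s in self.stages)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "tool_version": self.tool_version,
                "stages": [vars(s) for s in self.stages],
                "output_digests": self.output_digests,
                "warnings": self.warnings,
            },
            indent=2,
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _provenance(cfg: AnalysisConfig, inputs: list[str]) -> str:
    return "\n".join(
        [
            f"gapscope {__version__}",
            f"config_hash {cfg.config_hash()}",
            "inputs " + " ".join(inputs),
        ]
    )


class _Context:
    """Shared objects flowing between stages of one run."""

    def __init__(self, config: dict, out_dir: Path):
        self.config = config
        self.out_dir = out_dir
        self.analysis = AnalysisConfig.from_dict(config.get("analysis", {}))
        self.truth = None
        self.draft_truth = None

    # ---- input resolution: explicit config paths win; simulate outputs next

    def draft_seqs(self):
        if "draft" in self.config:
            return read_fasta(self.config["draft"])
        if self.draft_truth is not None:
            return self.draft_truth.draft
        raise FileNotFoundError("no draft assembly: run simulate or set config['draft']")

    def ref_seqs(self):
        if "reference" in self.config:
            return read_fasta(self.config["reference"])
        if self.truth is not None:
            return self.truth.genome
        raise FileNotFoundError("no reference: run simulate or set config['reference']")


def _stage_simulate(ctx: _Context) -> list[Path]:
    sim_cfg = SimulationConfig(**ctx.config.get("sim", {}))
    ctx.truth = build_truth_genome(sim_cfg)
    ctx.draft_truth = derive_draft(ctx.truth)
    out = ctx.out_dir
    outputs = []

    write_fasta(ctx.truth.genome, out / "truth.fa")
    write_fasta(ctx.draft_truth.draft, out / "draft.fa")
    outputs += [out / "truth.fa", out / "draft.fa"]

    prov = _provenance(ctx.analysis, ["<simulated>"])
    write_bed(
        [(r.interval, r.repeat_class.name) for r in ctx.truth.repeats],
        out / "truth.repeats.bed", provenance=prov,
    )
    write_bed(
        [(r.interval, r.repeat_class.name) for r in ctx.draft_truth.draft_repeats],
        out / "draft.repeats.bed", provenance=prov,
    )
    outputs += [out / "truth.repeats.bed", out / "draft.repeats.bed"]

    with open(out / "gap_truth.tsv", "w") as fh:
        fh.write("# " + prov.replace("\n", "\n# ") + "\n")
        fh.write("scaffold\tstart\tend\tcause\tsource\texpect_not_scorable\ttag\n")
        for g in ctx.draft_truth.gap_truth:
            src = f"{g.source[0]}:{g.source[1]}-{g.source[2]}" if g.source else "."
            fh.write(
                f"{g.scaffold}\t{g.start}\t{g.end}\t{g.cause}\t{src}\t"
                f"{g.expect_not_scorable or '.'}\t{g.tag or '.'}\n"
            )
    outputs.append(out / "gap_truth.tsv")

    depth = float(ctx.config.get("depth", 30.0))
    cov = simulate_coverage_table(ctx.draft_truth, depth=depth, seed=sim_cfg.seed)
    cov.to_tsv(out / "depth.tsv", provenance=prov)
    outputs.append(out / "depth.tsv")

    with open(out / "exons.faa", "w") as fh:
        for i, q in enumerate(ctx.truth.exon_queries):
            fh.write(f">exon_query_{i}\n{q}\n")
    with open(out / "genes.faa", "w") as fh:
        for gene_id, info in ctx.truth.genes.items():
            fh.write(f">{gene_id}\n{info['protein']}\n")
    outputs += [out / "exons.faa", out / "genes.faa"]
    return outputs


def _stage_stats(ctx: _Context) -> list[Path]:
    draft = ctx.draft_seqs()
    stats = assembly_summary(draft, ctx.analysis)
    rows = [("draft", stats)]
    try:
        ref = ctx.ref_seqs()
        ref_stats = assembly_summary(ref, ctx.analysis)
        rows.append(("reference", ref_stats))
        missing = missing_fraction(stats, ref_stats)
    except FileNotFoundError:
        missing = None
    path = ctx.out_dir / "stats.tsv"
    with open(path, "w") as fh:
        fh.write("# " + _provenance(ctx.analysis, ["draft"]).replace("\n", "\n# ") + "\n")
        fh.write(
            "assembly\tscaffold_count\tcontig_count\tscaffold_n50\tcontig_n50\t"
            "total_len\ttotal_len_no_n\tgap_count\tgap_bp\tmissing_pct\n"
        )
        for name, s in rows:
            m = f"{missing:.3f}" if (name == "draft" and missing is not None) else "."
            fh.write(
                f"{name}\t{s.scaffold_count}\t{s.contig_count}\t{s.scaffold_n50}\t"
                f"{s.contig_n50}\t{s.total_len}\t{s.total_len_no_n}\t{s.gap_count}\t"
                f"{s.gap_bp}\t{m}\n"
            )
    return [path]


def _stage_gapcause(ctx: _Context) -> list[Path]:
    draft = ctx.draft_seqs()
    ref = ctx.ref_seqs()
    if ctx.draft_truth is not None:
        draft_repeats = ctx.draft_truth.draft_repeats
        ref_repeats = ctx.truth.repeats
    else:
        from .genome_io import read_repeatmasker_out

        draft_repeats = read_repeatmasker_out(ctx.config["draft_repeats"], draft)
        ref_repeats = read_repeatmasker_out(ctx.config["ref_repeats"], ref)
    result = run_gap_analysis(draft, ref, draft_repeats, ref_repeats, ctx.analysis)
    tables = tabulate_gap_causes(result.adjacency, result.content)
    prov = "# " + _provenance(ctx.analysis, ["draft", "reference"]).replace("\n", "\n# ") + "\n"
    outputs = []
    for name, df in tables.items():
        path = ctx.out_dir / f"gapcause.{name}.tsv"
        with open(path, "w") as fh:
            fh.write(prov)
            df.to_csv(fh, sep="\t", index=False)
        outputs.append(path)
    bed_path = ctx.out_dir / "gapcause.placements.bed"
    write_bed(
        [
            (p.projected, f"{g.scaffold}:{g.start}-{g.end}")
            for g, p in result.placements.items()
            if p.projected is not None
        ],
        bed_path,
        provenance=_provenance(ctx.analysis, ["draft", "reference"]),
    )
    outputs.append(bed_path)
    summary = {
        "gaps_analyzed": len(result.gaps),
        "scorable": sum(1 for l in result.content.values() if l.scorable),
        "collapsed_to_zero": result.collapsed_to_zero,
    }
    path = ctx.out_dir / "gapcause.summary.json"
    path.write_text(json.dumps(summary, indent=2))
    outputs.append(path)
    return outputs


def _stage_gc(ctx: _Context) -> list[Path]:
    draft = ctx.draft_seqs()
    res = gc_windows(draft, ctx.analysis)
    path = ctx.out_dir / "gc_windows.tsv"
    with open(path, "w") as fh:
        fh.write("# " + _provenance(ctx.analysis, ["draft"]).replace("\n", "\n# ") + "\n")
        fh.write(f"# above_{ctx.analysis.gc_threshold}: {res.above_threshold}\n")
        fh.write(f"# above_{ctx.analysis.gc_threshold_alt}: {res.above_threshold_alt}\n")
        fh.write(f"# excluded_windows: {res.excluded_windows}\n")
        res.table.to_csv(fh, sep="\t", index=False)
    return [path]


def _stage_g4(ctx: _Context) -> list[Path]:
    draft = ctx.draft_seqs()
    motifs = find_g4_motifs(draft)
    path = ctx.out_dir / "g4_canonical.bed"
    write_bed(
        [(m.interval, f"g4_canonical_{m.n_tracts}tracts") for m in motifs],
        path,
        provenance=_provenance(ctx.analysis, ["draft"]),
    )
    summary_path = ctx.out_dir / "g4_summary.json"
    summary_path.write_text(json.dumps(g4_summary(motifs), indent=2))
    return [path, summary_path]


def _read_faa(path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name:
            out[name] += line.strip()
    return out


def _stage_census(ctx: _Context) -> list[Path]:
    draft = ctx.draft_seqs()
    if "exon_queries" in ctx.config:
        queries = list(_read_faa(ctx.config["exon_queries"]).values())
    elif ctx.truth is not None:
        queries = ctx.truth.exon_queries
    else:
        raise FileNotFoundError("no exon queries: run simulate or set config['exon_queries']")
    spec = ctx.analysis.exon_queries[0]
    qset = ExonQuerySet(spec.name, spec.query_alignment_length, spec.min_hit_len, queries)
    res = exon_census(qset, draft, ctx.analysis)
    path = ctx.out_dir / "census.tsv"
    with open(path, "w") as fh:
        fh.write("# " + _provenance(ctx.analysis, ["draft"]).replace("\n", "\n# ") + "\n")
        fh.write(f"# total_merged_intervals: {res.total}\n")
        res.table.to_csv(fh, sep="\t", index=False)
    return [path]


def _stage_genes(ctx: _Context) -> list[Path]:
    draft = ctx.draft_seqs()
    if "proteins" in ctx.config:
        models = _read_faa(ctx.config["proteins"])
    elif ctx.truth is not None:
        models = {g: info["protein"] for g, info in ctx.truth.genes.items()}
    else:
        raise FileNotFoundError("no gene models: run simulate or set config['proteins']")
    calls = gene_presence(models, draft, ctx.analysis)
    path = ctx.out_dir / "gene_presence.tsv"
    with open(path, "w") as fh:
        fh.write("# " + _provenance(ctx.analysis, ["draft"]).replace("\n", "\n# ") + "\n")
        fh.write("gene_id\tstatus\taligned_fraction\tsimilarity\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.status}\t{c.aligned_fraction:.2f}\t{c.similarity:.2f}\n")
    return [path]


def _stage_sexlink(ctx: _Context) -> list[Path]:
    if "depth" in ctx.config and isinstance(ctx.config["depth"], str):
        cov = CoverageTable.from_tsv(ctx.config["depth"])
    elif (ctx.out_dir / "depth.tsv").exists():
        cov = CoverageTable.from_tsv(ctx.out_dir / "depth.tsv")
    else:
        raise FileNotFoundError("no depth table: run simulate or set config['depth']")
    z_hom = None
    if "z_homology" in ctx.config:
        import pandas as pd

        zdf = pd.read_csv(ctx.config["z_homology"], sep="\t", comment="#",
                          names=["contig", "fraction"], header=None)
        z_hom = dict(zip(zdf["contig"].astype(str), zdf["fraction"].astype(float)))
    calls = classify_sex_linkage(cov, z_hom=z_hom, cfg=ctx.analysis)
    path = ctx.out_dir / "sexlink.tsv"
    with open(path, "w") as fh:
        fh.write("# " + _provenance(ctx.analysis, ["depth.tsv"]).replace("\n", "\n# ") + "\n")
        fh.write("# tolerance 0.25, w_male_max 0.1 (declared defaults)\n")
        fh.write("contig\tcall\tf_ratio\tm_ratio\tz_homology\n")
        for c in calls:
            zh = f"{c.z_homology:.3f}" if c.z_homology is not None else "."
            fh.write(f"{c.contig}\t{c.call}\t{c.f_ratio:.3f}\t{c.m_ratio:.3f}\t{zh}\n")
    outputs = [path]
    if ctx.draft_truth is not None:
        by_call = {c.contig: c for c in calls}
        comp = {
            scaf: [(name, by_call[name]) for name in names if name in by_call]
            for scaf, names in ctx.draft_truth.scaffold_composition.items()
        }
        flagged = flag_chimeric_scaffolds(comp)
        fpath = ctx.out_dir / "chimeric_scaffolds.txt"
        fpath.write_text("\n".join(flagged) + ("\n" if flagged else ""))
        outputs.append(fpath)
    return outputs


_STAGES = {
    "simulate": _stage_simulate,
    "stats": _stage_stats,
    "gapcause": _stage_gapcause,
    "gc": _stage_gc,
    "g4": _stage_g4,
    "census": _stage_census,
    "genes": _stage_genes,
    "sexlink": _stage_sexlink,
}


def run_pipeline(config: dict | str | Path, stages: list[str], out_dir) -> RunManifest:
    """Execute the requested stages in dependency order and write a manifest.

    ``config`` is a dict or a path to a JSON file. Data-consuming stages use
    explicit input paths from the config when given, otherwise the in-run
    simulator outputs; asking for them with neither is a dependency error
    recorded in the manifest.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in stages:
        if s not in _STAGES:
            raise ValueError(f"unknown stage name {s!r}")
    ordered = [s for s in STAGE_ORDER if s in stages]
    ctx = _Context(config, out_dir)
    manifest = RunManifest(config_hash=ctx.analysis.config_hash(), tool_version=__version__)
    simulate_failed = False
    for stage in ordered:
        if stage in _NEEDS_DATA and simulate_failed:
            manifest.stages.append(
                StageStatus(stage, "skipped", error="simulate stage failed upstream")
            )
            continue
        try:
            outputs = _STAGES[stage](ctx)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            log.error("stage %s failed: %s", stage, exc)
            log.debug("%s", traceback.format_exc())
            manifest.stages.append(StageStatus(stage, "failed", error=str(exc)))
            if stage == "simulate":
                simulate_failed = True
            continue
        paths = [str(p) for p in outputs]
        for p in outputs:
            manifest.output_digests[str(p)] = _digest(Path(p))
        manifest.stages.append(StageStatus(stage, "completed", outputs=paths))
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
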