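"""Seeded generator of avian-like truth genomes, repeat annotations,
fragmented drafts with known gap causes, and sex-resolved coverage tables.

The simulator emulates the genome architecture that makes bird assemblies
hard: AT-moderate macrochromosomes and GC-rich microchromosomes, a
repeat-rich W chromosome (~70% repeat density), satellite arrays of a short
tandem unit, LTR retrotransposons with near-identical terminal repeats,
5'-truncated LINEs, simple repeats, a tandem multicopy-exon cluster, and a
handful of single-exon protein-coding genes. A draft assembly is then
derived by excising or collapsing planted features and rejoining the pieces
with N gaps, so every draft gap has a known cause and a known source
interval on the truth genome.

Determinism: one RNG stream per (seed, stage-name), so adding stages never
perturbs earlier stages' draws, and all outputs are byte-identical under a
fixed config.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    GenomeSequences,
    Interval,
    RepeatAnnotation,
    RepeatClass,
    RepeatRecord,
)
from .local_align import revcomp
from .sex_linkage import CoverageRow, CoverageTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(stage.encode()) & 0x7FFFFFFF])


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only mutation at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        cur = arr[i]
        choices = [b for b in b"ACGT" if b != cur]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


@dataclass
class SimulationConfig:
    """Knobs of the truth-genome and draft simulator; defaults are the
    study conditions the rest of the package is validated against."""

    n_macro: int = 4
    n_micro: int = 4
    macro_len: int = 500_000
    micro_len: int = 100_000
    z_len: int = 300_000
    w_len: int = 150_000
    par_len: int = 30_000
    macro_gc: float = 42.0
    micro_gc: float = 60.0
    w_gc: float = 45.0
    include_sex: bool = True
    w_repeat_target: float = 70.0
    repeat_mix: dict = field(default_factory=dict)  # chrom class -> {class name: pct}
    ltr_len: int = 8000
    ltr_terminal: int = 800
    satellite_unit: int = 170
    line_full_len: int = 5000
    line_trunc_p: float = 0.4  # geometric 5'-truncation, kb-chunks from the 3' end
    n_exon_paralogs: int = 12
    n_truncated_paralogs: int = 1  # boundary-length copies the census must drop
    exon_codons: int = 90
    n_genes: int = 6
    mutation_rate: float = 0.0
    break_bias: dict = field(default_factory=dict)  # class name -> relative odds
    n_breaks: int = 200
    n_background_breaks: int = 12
    gap_n_len: int = 100
    min_spacer: int = 650
    seed: int = 1

    def __post_init__(self):
        for name in ("macro_gc", "micro_gc", "w_gc", "w_repeat_target"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} out of [0, 100]")
        for name in ("macro_len", "micro_len", "z_len", "w_len", "par_len",
                     "ltr_len", "satellite_unit", "line_full_len", "gap_n_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.repeat_mix:
            self.repeat_mix = self.default_repeat_mix()
        for cls_name, mix in self.repeat_mix.items():
            if sum(mix.values()) > 80:
                raise ValueError(f"repeat_mix for {cls_name} sums above 80%")

    def default_repeat_mix(self) -> dict:
        w = self.w_repeat_target
        return {
            "macro": {"LINE": 4.0, "LTR": 4.0, "Satellite": 1.5, "SimpleRepeat": 1.2, "DNA": 1.0},
            "micro": {"LINE": 2.0, "LTR": 2.0, "SimpleRepeat": 2.0},
            "Z": {"LINE": 4.0, "LTR": 4.0, "Satellite": 1.5, "SimpleRepeat": 1.2, "DNA": 1.0},
            "W": {
                "Satellite": 0.50 * w,
                "LTR": 0.20 * w,
                "LINE": 0.25 * w,
                "SimpleRepeat": 0.05 * w,
            },
            "PAR-segment": {"LINE": 3.0, "SimpleRepeat": 1.0},
        }


@dataclass
class PlantedFeature:
    """One planted element in truth coordinates (set after layout)."""

    kind: str  # repeat | exon | gene | dup | exon_trunc
    seq: str
    repeat_class: RepeatClass | None = None
    family: str = ""
    full_length: bool = False
    divergence: float = 0.0
    breakable: bool = False
    group: int | None = None  # complex-pair group id
    payload: dict = field(default_factory=dict)
    chrom: str = ""
    start: int = -1
    end: int = -1


@dataclass
class SyntheticTruth:
    genome: GenomeSequences
    repeats: RepeatAnnotation
    exon_paralogs: list  # (Interval, strand, paralog_id)
    exon_queries: list[str]  # protein queries for the paralog census
    genes: dict[str, dict]  # gene_id -> {interval, strand, protein}
    chromosome_table: dict[str, str]  # name -> macro|micro|Z|W|PAR-segment
    features: list[PlantedFeature]
    spacers: dict[str, list[tuple[int, int]]]  # background intervals per chrom
    duplicated_segment: tuple[Interval, Interval] | None
    config: SimulationConfig


# ---------------------------------------------------------------------------
# feature construction

def _g4_free_dna(rng, length: int, gc: float, tandem: bool = False) -> str:
    """Background/consensus sequence free of canonical G4 motifs on either
    strand, so the simulated G4 signal tracks chromosome base composition
    rather than which chromosome happened to receive repeat arrays."""
    from .base_composition import _g4_pattern

    pat = _g4_pattern(7)
    for _ in range(50):
        seq = random_dna(rng, length, gc)
        probe = seq + seq if tandem else seq
        rc = revcomp(probe)
        if pat.search(probe) is None and pat.search(rc) is None:
            return seq
    raise RuntimeError("could not draw a G4-free sequence")  # pragma: no cover


class _Families:
    """Per-genome consensus sequences for repeat families."""

    def __init__(self, rng, cfg: SimulationConfig):
        internal = cfg.ltr_len - 2 * cfg.ltr_terminal
        self.ltr_tr = [_g4_free_dna(rng, cfg.ltr_terminal, 0.45) for _ in range(2)]
        self.ltr_internal = [_g4_free_dna(rng, internal, 0.45) for _ in range(2)]
        self.line = [_g4_free_dna(rng, cfg.line_full_len, 0.42) for _ in range(2)]
        self.satellite = [_g4_free_dna(rng, cfg.satellite_unit, 0.48, tandem=True) for _ in range(2)]
        self.dna_tp = [_g4_free_dna(rng, 1500, 0.45)]


def _ltr_element(rng, fam: _Families, cfg) -> PlantedFeature:
    """A full-length LTR retrotransposon: two terminal repeats >= 99%
    identical flank a mutated internal region; per-copy divergence ~3%."""
    f = int(rng.integers(len(fam.ltr_tr)))
    tr = mutate(rng, fam.ltr_tr[f], 0.03)
    tr2 = mutate(rng, tr, 0.004)
    internal = mutate(rng, fam.ltr_internal[f], 0.03)
    return PlantedFeature(
        "repeat", tr + internal + tr2, RepeatClass.LTR, f"LTR_fam{f}",
        full_length=True, divergence=3.0, breakable=True,
        payload={"mode": "ltr"},
    )


def _ltr_fragment(rng, fam: _Families, max_len: int) -> PlantedFeature:
    f = int(rng.integers(len(fam.ltr_internal)))
    cons = fam.ltr_internal[f]
    size = int(min(max(800, rng.integers(800, 2500)), max_len, len(cons)))
    start = int(rng.integers(0, len(cons) - size + 1))
    return PlantedFeature(
        "repeat", mutate(rng, cons[start : start + size], 0.03),
        RepeatClass.LTR, f"LTR_fam{f}", full_length=False, divergence=3.0,
        breakable=True, payload={"mode": "delete_only"},
    )


def _line_copy(rng, fam: _Families, cfg, max_len: int) -> PlantedFeature:
    f = int(rng.integers(len(fam.line)))
    chunks = int(rng.geometric(cfg.line_trunc_p))
    keep = min(chunks * 1000, cfg.line_full_len, max_len)
    keep = max(keep, 500)
    cons = fam.line[f]
    return PlantedFeature(
        "repeat", mutate(rng, cons[len(cons) - keep :], 0.04),  # 3' end retained
        RepeatClass.LINE, f"LINE_fam{f}", divergence=4.0, breakable=True,
        payload={"mode": "line"},
    )


def _satellite_array(rng, fam: _Families, cfg, target: int) -> PlantedFeature:
    f = int(rng.integers(len(fam.satellite)))
    unit = fam.satellite[f]
    n_units = int(np.clip(round(target / len(unit)), 5, 40))
    parts = [mutate(rng, unit, rng.uniform(0, 0.02)) for _ in range(n_units)]
    return PlantedFeature(
        "repeat", "".join(parts), RepeatClass.Satellite, f"SAT_fam{f}",
        divergence=1.0, breakable=True,
        payload={"mode": "collapse", "unit": len(unit), "n_units": n_units},
    )


def _simple_repeat(rng, max_len: int) -> PlantedFeature:
    motif_len = int(rng.integers(2, 7))
    while True:  # no GG/CC in the tiled pattern: G-tract arrays would read as G4
        motif = random_dna(rng, motif_len, 0.5)
        if "GG" not in motif + motif and "CC" not in motif + motif:
            break
    size = int(min(rng.integers(80, 401), max_len))
    seq = (motif * (size // motif_len + 1))[:size]
    return PlantedFeature(
        "repeat", seq, RepeatClass.SimpleRepeat, f"({motif})n",
        divergence=0.0, breakable=True, payload={"mode": "collapse", "unit": motif_len},
    )


def _dna_copy(rng, fam: _Families, max_len: int) -> PlantedFeature:
    cons = fam.dna_tp[0]
    size = int(min(len(cons), max_len))
    return PlantedFeature(
        "repeat", mutate(rng, cons[:size], 0.05), RepeatClass.DNA, "DNA_fam0",
        divergence=5.0, breakable=True, payload={"mode": "delete_only"},
    )


def _plan_repeats(rng, fam, cfg, chrom_class: str, chrom_len: int) -> list[PlantedFeature]:
    feats: list[PlantedFeature] = []
    mix = cfg.repeat_mix.get(chrom_class, {})
    for cls_name, pct in mix.items():
        target = int(pct / 100 * chrom_len)
        planted = 0
        while planted < target:
            remaining = target - planted
            if cls_name == "LTR":
                if remaining >= cfg.ltr_len:
                    ft = _ltr_element(rng, fam, cfg)
                elif remaining >= 800:
                    ft = _ltr_fragment(rng, fam, remaining)
                else:
                    break
            elif cls_name == "LINE":
                if remaining < 500:
                    break
                ft = _line_copy(rng, fam, cfg, remaining)
            elif cls_name == "Satellite":
                if remaining < 5 * cfg.satellite_unit:
                    break
                ft = _satellite_array(rng, fam, cfg, min(remaining, int(rng.integers(3000, 6001))))
            elif cls_name == "SimpleRepeat":
                if remaining < 80:
                    break
                ft = _simple_repeat(rng, remaining)
            elif cls_name == "DNA":
                if remaining < 600:
                    break
                ft = _dna_copy(rng, fam, remaining)
            else:
                raise ValueError(f"no generator for repeat class {cls_name}")
            feats.append(ft)
            planted += len(ft.seq)
    return feats


def _complex_pair(rng, fam, cfg, group: int) -> list[PlantedFeature]:
    """An LTR fragment and a simple repeat 50 bp apart; breaking the pair
    excises both, producing a Complex-cause gap."""
    a = _ltr_fragment(rng, fam, 1200)
    b = _simple_repeat(rng, 300)
    spacer = random_dna(rng, 50, 0.45)
    a.group = b.group = group
    a.breakable = b.breakable = False  # broken via the group, not singly
    a.payload["complex_spacer_after"] = spacer
    return [a, b]


def _random_codons(rng, n: int) -> str:
    out = []
    while len(out) < n:
        codon = random_dna(rng, 3, 0.5)
        if codon not in _STOPS and codon != "ATG":
            out.append(codon)
    return "".join(out)


def _mutate_codons(rng, codons: str, n_mut: int, lo_codon: int, hi_codon: int) -> str:
    """Mutate n_mut random bases within codons [lo_codon, hi_codon), never
    creating a stop codon."""
    arr = list(codons)
    done = 0
    while done < n_mut:
        ci = int(rng.integers(lo_codon, hi_codon))
        pos = 3 * ci + int(rng.integers(3))
        old = arr[pos]
        new = "ACGT"[int(rng.integers(4))]
        if new == old:
            continue
        arr[pos] = new
        if "".join(arr[3 * ci : 3 * ci + 3]) in _STOPS:
            arr[pos] = old
            continue
        done += 1
    return "".join(arr)


def _translate(codons: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codons).translate())


# ---------------------------------------------------------------------------
# truth genome

def build_truth_genome(cfg: SimulationConfig) -> SyntheticTruth:
    """Deterministically build the annotated truth genome for a config."""
    rng_fam = _stage_rng(cfg.seed, "families")
    fam = _Families(rng_fam, cfg)

    chroms: list[tuple[str, str, int, float]] = []  # name, class, len, gc
    for i in range(cfg.n_macro):
        chroms.append((f"macro{i + 1}", "macro", cfg.macro_len, cfg.macro_gc / 100))
    for i in range(cfg.n_micro):
        chroms.append((f"micro{i + 1}", "micro", cfg.micro_len, cfg.micro_gc / 100))
    if cfg.include_sex:
        chroms.append(("chrZ", "Z", cfg.z_len, cfg.macro_gc / 100))
        chroms.append(("chrW", "W", cfg.w_len, cfg.w_gc / 100))
        chroms.append(("chrZ_PAR", "PAR-segment", cfg.par_len, cfg.macro_gc / 100))

    # exon-paralog cluster (codons flanked by in-frame stops so translated
    # hit boundaries are exact)
    rng_exon = _stage_rng(cfg.seed, "exons")
    exon_codons = _random_codons(rng_exon, cfg.exon_codons)
    exon_queries = [
        _translate(exon_codons),
        _translate(_mutate_codons(rng_exon, exon_codons, 4, 0, cfg.exon_codons)),
    ]
    paralog_feats: list[PlantedFeature] = []
    for p in range(cfg.n_exon_paralogs):
        n_mut = int(rng_exon.integers(5, 22))  # ~2-8% nucleotide divergence
        codons = _mutate_codons(rng_exon, exon_codons, n_mut, 0, cfg.exon_codons)
        strand = "+" if rng_exon.random() < 0.5 else "-"
        paralog_feats.append(
            PlantedFeature("exon", "TAA" + codons + "TAA", breakable=False,
                           payload={"strand": strand, "paralog_id": f"paralog_{p}"})
        )
    for p in range(cfg.n_truncated_paralogs):
        # first 80 codons, ends kept exact: insertion-free hit length is
        # exactly 240 nt, the boundary the census must exclude
        codons = _mutate_codons(rng_exon, exon_codons[: 80 * 3], 5, 10, 70)
        paralog_feats.append(
            PlantedFeature("exon_trunc", "TAA" + codons + "TAA", breakable=False,
                           payload={"strand": "+", "paralog_id": f"trunc_{p}"})
        )

    # single-exon genes
    rng_gene = _stage_rng(cfg.seed, "genes")
    gene_feats: list[PlantedFeature] = []
    for g in range(cfg.n_genes):
        n_codon = int(rng_gene.integers(200, 321))
        codons = "ATG" + _random_codons(rng_gene, n_codon) + "TAA"
        gene_feats.append(
            PlantedFeature("gene", codons, breakable=False,
                           payload={"gene_id": f"gene_{g}", "protein": _translate(codons[:-3])})
        )

    # duplicated 500-bp segment: identical copies on two macrochromosomes
    rng_dup = _stage_rng(cfg.seed, "duplication")
    dup_seq = random_dna(rng_dup, 500, 0.45)
    dup_feats = [
        PlantedFeature("dup", dup_seq, breakable=False, payload={"copy": i}) for i in range(2)
    ]

    rng_plant = _stage_rng(cfg.seed, "planting")
    records: dict[str, str] = {}
    chromosome_table: dict[str, str] = {}
    all_features: list[PlantedFeature] = []
    spacers: dict[str, list[tuple[int, int]]] = {}
    group_counter = 0

    for ci, (name, chrom_class, length, gc) in enumerate(chroms):
        feats = _plan_repeats(rng_plant, fam, cfg, chrom_class, length)
        if chrom_class == "macro":
            for _ in range(2):  # complex pairs on every macrochromosome
                group_counter += 1
                feats.extend(_complex_pair(rng_plant, fam, cfg, group_counter))
        if name == "micro1":
            feats.extend(paralog_feats)
        if name == "macro1":
            feats.append(dup_feats[0])
        if name == "macro2":
            feats.append(dup_feats[1])
        # spread genes over macrochromosomes
        for gi, gf in enumerate(gene_feats):
            if chrom_class == "macro" and gi % cfg.n_macro == ci:
                feats.append(gf)

        order = rng_plant.permutation(len(feats))
        feats = [feats[i] for i in order]
        # complex-pair members must stay adjacent: re-join groups
        grouped: list[list[PlantedFeature]] = []
        seen_groups: dict[int, list[PlantedFeature]] = {}
        for ft in feats:
            if ft.group is None:
                grouped.append([ft])
            elif ft.group in seen_groups:
                seen_groups[ft.group].append(ft)
            else:
                seen_groups[ft.group] = [ft]
                grouped.append(seen_groups[ft.group])
        for members in grouped:  # pair member carrying the internal spacer leads
            if len(members) == 2 and "complex_spacer_after" not in members[0].payload:
                members.reverse()

        total_block = sum(
            sum(len(ft.seq) for ft in members)
            + (len(members[0].payload["complex_spacer_after"]) if len(members) == 2 else 0)
            for members in grouped
        )
        n_sp = len(grouped) + 1
        budget = length - total_block
        if budget < cfg.min_spacer * n_sp:
            raise ValueError(f"infeasible repeat mix: {name} cannot hold planted features")
        extra = rng_plant.multinomial(budget - cfg.min_spacer * n_sp, [1 / n_sp] * n_sp)
        spacer_lens = [cfg.min_spacer + int(e) for e in extra]

        parts: list[str] = []
        pos = 0
        chrom_spacers: list[tuple[int, int]] = []
        for bi, members in enumerate(grouped):
            sp = random_dna(rng_plant, spacer_lens[bi], gc)
            chrom_spacers.append((pos, pos + len(sp)))
            parts.append(sp)
            pos += len(sp)
            for mi, ft in enumerate(members):
                emitted = ft.seq
                if ft.kind in ("exon", "exon_trunc") and ft.payload["strand"] == "-":
                    emitted = revcomp(ft.seq)
                ft.chrom, ft.start, ft.end = name, pos, pos + len(emitted)
                parts.append(emitted)
                pos += len(emitted)
                all_features.append(ft)
                if len(members) == 2 and mi == 0:
                    isp = ft.payload["complex_spacer_after"]
                    parts.append(isp)
                    pos += len(isp)
        sp = random_dna(rng_plant, spacer_lens[-1], gc)
        chrom_spacers.append((pos, pos + len(sp)))
        parts.append(sp)
        pos += len(sp)
        seq = "".join(parts)
        assert len(seq) == length, (name, len(seq), length)
        records[name] = seq
        chromosome_table[name] = chrom_class
        spacers[name] = chrom_spacers

    genome = GenomeSequences(records, source_path="<synthetic>")

    repeat_records = [
        RepeatRecord(
            Interval(ft.chrom, ft.start, ft.end, "+"),
            ft.repeat_class, ft.family, ft.full_length, ft.divergence,
        )
        for ft in all_features
        if ft.kind == "repeat"
    ]
    exon_paralogs = [
        (Interval(ft.chrom, ft.start + 3, ft.end - 3), ft.payload["strand"], ft.payload["paralog_id"])
        for ft in all_features
        if ft.kind == "exon"
    ]
    genes = {
        ft.payload["gene_id"]: {
            "interval": Interval(ft.chrom, ft.start, ft.end),
            "strand": "+",
            "protein": ft.payload["protein"],
        }
        for ft in all_features
        if ft.kind == "gene"
    }
    dup_iv = [
        Interval(ft.chrom, ft.start, ft.end) for ft in all_features if ft.kind == "dup"
    ]
    truth = SyntheticTruth(
        genome=genome,
        repeats=RepeatAnnotation(repeat_records),
        exon_paralogs=exon_paralogs,
        exon_queries=exon_queries,
        genes=genes,
        chromosome_table=chromosome_table,
        features=all_features,
        spacers=spacers,
        duplicated_segment=(dup_iv[0], dup_iv[1]) if len(dup_iv) == 2 else None,
        config=cfg,
    )
    return truth


# ---------------------------------------------------------------------------
# draft derivation

@dataclass
class GapTruth:
    """Ground truth for one draft gap: its cause and source interval."""

    scaffold: str
    start: int  # draft coordinates of the N-run
    end: int
    cause: str  # repeat class name, Complex, or NoRepeat
    source: tuple[str, int, int] | None  # excised truth interval
    expect_not_scorable: str | None = None
    tag: str = ""


@dataclass
class _Excision:
    chrom: str
    start: int
    end: int
    cause: str
    tag: str = ""
    expect: str | None = None
    forced: bool = False


@dataclass
class DraftTruth:
    draft: GenomeSequences
    gap_truth: list[GapTruth]
    contig_map: list[tuple]  # (scaffold, d_start, d_end, chrom, t_start, t_end, strand)
    draft_repeats: RepeatAnnotation
    scaffold_composition: dict[str, list[str]]
    contig_table: list[tuple[str, int, str]]  # contig name, length, chromosome class
    truth: SyntheticTruth


def _plan_excisions(truth: SyntheticTruth, rng) -> list[_Excision]:
    cfg = truth.config
    excisions: list[_Excision] = []

    # forced: ambiguity break right after the first duplicated-segment copy
    if truth.duplicated_segment is not None:
        seg = truth.duplicated_segment[0]
        excisions.append(
            _Excision(seg.seq_name, seg.end, seg.end + 120, "NoRepeat",
                      tag="dup_ambiguous", expect="ambiguous", forced=True)
        )
    # forced: one gene split mid-sequence, one gene fully excised
    gene_ids = sorted(truth.genes)
    if len(gene_ids) >= 2:
        g0 = truth.genes[gene_ids[0]]["interval"]
        L = len(g0)
        excisions.append(
            _Excision(g0.seq_name, g0.start + int(0.3 * L), g0.start + int(0.7 * L),
                      "NoRepeat", tag="gene_split", forced=True)
        )
        g1 = truth.genes[gene_ids[1]]["interval"]
        excisions.append(
            _Excision(g1.seq_name, max(0, g1.start - 50), g1.end + 50,
                      "NoRepeat", tag="gene_absent", forced=True)
        )

    # breakable units: single repeat features plus complex pairs (one unit each)
    units: list[tuple] = []
    groups: dict[int, list[PlantedFeature]] = {}
    for ft in truth.features:
        if ft.group is not None:
            groups.setdefault(ft.group, []).append(ft)
        elif ft.breakable:
            units.append(("single", ft))
    for members in groups.values():
        members.sort(key=lambda f: f.start)
        units.append(("complex", members))

    weights = np.array(
        [
            truth.config.break_bias.get(
                u[1].repeat_class.name if u[0] == "single" else "Complex", 1.0
            )
            for u in units
        ],
        dtype=float,
    )
    n_take = min(cfg.n_breaks, len(units))
    if weights.sum() <= 0:
        raise ValueError("break_bias leaves no breakable features")
    idx = rng.choice(len(units), size=n_take, replace=False, p=weights / weights.sum())
    for i in sorted(idx.tolist()):
        kind, obj = units[i]
        if kind == "complex":
            m1, m2 = rng.integers(20, 76), rng.integers(20, 76)
            excisions.append(
                _Excision(obj[0].chrom, obj[0].start - int(m1), obj[-1].end + int(m2), "Complex")
            )
            continue
        ft = obj
        mode = ft.payload.get("mode", "delete_only")
        flen = ft.end - ft.start
        if mode == "collapse":
            keep = 2 * ft.payload["unit"] if ft.repeat_class is RepeatClass.Satellite else 30
            excisions.append(
                _Excision(ft.chrom, ft.start + keep, ft.end, ft.repeat_class.name)
            )
        elif mode == "ltr" and rng.random() < 0.5 and flen >= 2 * 1300 + 200:
            # split inside the internal region: flanks stay clear of the
            # near-identical terminal repeats
            excisions.append(
                _Excision(ft.chrom, ft.start + 1300, ft.end - 1300, ft.repeat_class.name)
            )
        elif mode == "line" and rng.random() < 0.4 and flen >= 2600:
            excisions.append(
                _Excision(ft.chrom, ft.start + 300, ft.end - 300, ft.repeat_class.name)
            )
        else:  # delete the whole feature plus small margins into the spacers
            m1, m2 = rng.integers(20, 76), rng.integers(20, 76)
            excisions.append(
                _Excision(ft.chrom, ft.start - int(m1), ft.end + int(m2), ft.repeat_class.name)
            )

    # background breaks in long spacers
    candidates = [
        (chrom, s, e)
        for chrom, sps in truth.spacers.items()
        for s, e in sps
        if e - s >= 1400
    ]
    if candidates and cfg.n_background_breaks:
        take = min(cfg.n_background_breaks, len(candidates))
        for i in rng.choice(len(candidates), size=take, replace=False):
            chrom, s, e = candidates[int(i)]
            mid = (s + e) // 2
            excisions.append(_Excision(chrom, mid - 100, mid + 100, "NoRepeat"))

    # conflict resolution: keep excisions >= 500 bp apart (one flank length)
    # so no flank ever contains another excision's N-run
    by_chrom: dict[str, list[_Excision]] = {}
    for ex in excisions:
        by_chrom.setdefault(ex.chrom, []).append(ex)
    kept: list[_Excision] = []
    for chrom in sorted(by_chrom):
        row = sorted(by_chrom[chrom], key=lambda x: x.start)
        chosen: list[_Excision] = []
        for ex in row:
            if chosen and ex.start - chosen[-1].end < 500:
                if ex.forced and not chosen[-1].forced:
                    chosen[-1] = ex
                continue
            chosen.append(ex)
        kept.extend(chosen)
    return kept


def derive_draft(truth: SyntheticTruth) -> DraftTruth:
    """Break the truth genome at planted features and rejoin the pieces with
    N gaps, recording cause and source for every junction; optionally plant
    one chimeric scaffold joining a W contig with an autosomal contig."""
    cfg = truth.config
    rng = _stage_rng(cfg.seed, "breaks")
    rng_mut = _stage_rng(cfg.seed, "mutation")
    excisions = _plan_excisions(truth, rng)

    # per-chromosome contig segments and the junction between consecutive ones
    per_chrom: dict[str, dict] = {}
    for chrom, seq in truth.genome.items():
        exs = sorted([e for e in excisions if e.chrom == chrom], key=lambda x: x.start)
        segments: list[tuple[int, int]] = []
        pos = 0
        for ex in exs:
            segments.append((pos, ex.start))
            pos = ex.end
        segments.append((pos, len(seq)))
        per_chrom[chrom] = {"segments": segments, "junctions": exs}

    # scaffold plans: contig lists plus junction metadata (None = joint
    # introduced by scaffolding, not by an excision)
    scaffolds: dict[str, dict] = {}
    for chrom in truth.genome.names():
        info = per_chrom[chrom]
        contigs = [(chrom, s, e) for s, e in info["segments"] if e > s]
        junctions: list[_Excision | None] = list(info["junctions"])[: max(0, len(contigs) - 1)]
        scaffolds[f"scaf_{chrom}"] = {"contigs": contigs, "junctions": junctions}

    # chimeric scaffold: relocate the terminal contig of the last
    # macrochromosome onto the W scaffold (its former junction gap vanishes)
    if cfg.include_sex and "scaf_chrW" in scaffolds:
        donor = f"scaf_macro{cfg.n_macro}"
        d = scaffolds.get(donor)
        if d and len(d["contigs"]) >= 2:
            moved = d["contigs"].pop()
            d["junctions"].pop()
            w = scaffolds["scaf_chrW"]
            w["contigs"].append(moved)
            w["junctions"].append(
                _Excision("chrW", -1, -1, "NoRepeat", tag="chimera_junction",
                          expect="different_scaffolds")
            )

    gap_n = "N" * cfg.gap_n_len
    records: dict[str, str] = {}
    gap_truth: list[GapTruth] = []
    contig_map: list[tuple] = []
    composition: dict[str, list[str]] = {}
    contig_table: list[tuple[str, int, str]] = []
    counter: dict[str, int] = {}

    for scaf, plan in scaffolds.items():
        parts: list[str] = []
        pos = 0
        names: list[str] = []
        for ci, (chrom, s, e) in enumerate(plan["contigs"]):
            if ci > 0:
                ex = plan["junctions"][ci - 1]
                gap_truth.append(
                    GapTruth(
                        scaffold=scaf, start=pos, end=pos + cfg.gap_n_len,
                        cause=ex.cause if ex is not None else "NoRepeat",
                        source=(ex.chrom, ex.start, ex.end)
                        if ex is not None and ex.start >= 0
                        else None,
                        expect_not_scorable=ex.expect if ex is not None else None,
                        tag=ex.tag if ex is not None else "",
                    )
                )
                parts.append(gap_n)
                pos += cfg.gap_n_len
            piece = mutate(rng_mut, truth.genome[chrom][s:e], cfg.mutation_rate)
            n = counter.get(chrom, 0)
            counter[chrom] = n + 1
            cname = f"{chrom}_ctg{n}"
            names.append(cname)
            contig_map.append((scaf, pos, pos + (e - s), chrom, s, e, "+"))
            contig_table.append((cname, e - s, truth.chromosome_table[chrom]))
            parts.append(piece)
            pos += e - s
        records[scaf] = "".join(parts)
        composition[scaf] = names

    draft = GenomeSequences(records, source_path="<synthetic draft>")
    draft_repeats = _map_repeats_to_draft(truth, contig_map)
    return DraftTruth(draft, gap_truth, contig_map, draft_repeats, composition,
                      contig_table, truth)


def _map_repeats_to_draft(truth: SyntheticTruth, contig_map: list[tuple]) -> RepeatAnnotation:
    """Project truth repeat annotations onto draft coordinates; a feature
    keeps its full-length flag only when wholly contained in one contig."""
    by_chrom: dict[str, list[tuple]] = {}
    for entry in contig_map:
        by_chrom.setdefault(entry[3], []).append(entry)
    records = []
    for rec in truth.repeats:
        iv = rec.interval
        for scaf, d_s, d_e, chrom, t_s, t_e, _strand in by_chrom.get(iv.seq_name, []):
            lo, hi = max(iv.start, t_s), min(iv.end, t_e)
            if lo >= hi:
                continue
            intact = t_s <= iv.start and iv.end <= t_e
            records.append(
                RepeatRecord(
                    Interval(scaf, d_s + (lo - t_s), d_s + (hi - t_s), "+"),
                    rec.repeat_class, rec.family_name,
                    full_length=rec.full_length and intact,
                    divergence=rec.divergence,
                )
            )
    return RepeatAnnotation(records)


# ---------------------------------------------------------------------------
# coverage simulation

#: (female, male) ploidy factors relative to the autosomal diploid baseline
PLOIDY_FACTORS = {
    "macro": (1.0, 1.0),
    "micro": (1.0, 1.0),
    "PAR-segment": (1.0, 1.0),
    "Z": (0.5, 1.0),
    "W": (0.5, 0.0),
}


def _contig_list(source) -> list[tuple[str, int, str]]:
    if isinstance(source, DraftTruth):
        return source.contig_table
    if isinstance(source, SyntheticTruth):
        return [
            (name, len(seq), source.chromosome_table[name])
            for name, seq in source.genome.items()
        ]
    raise TypeError("source must be SyntheticTruth or DraftTruth")


def simulate_coverage(source, depth: float, sex: str, seed: int) -> dict[str, float]:
    """Per-contig mean read depth for one sex: Poisson(length * d) / length,
    with d = depth * ploidy factor (autosome/PAR 1.0 in both sexes; Z 0.5 in
    the female; W 0.5 female / 0.0 male)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if sex not in ("female", "male"):
        raise ValueError("sex must be 'female' or 'male'")
    rng = _stage_rng(seed, f"coverage-{sex}")
    col = 0 if sex == "female" else 1
    out: dict[str, float] = {}
    for name, length, cls in _contig_list(source):
        d = depth * PLOIDY_FACTORS[cls][col]
        out[name] = float(rng.poisson(length * d)) / length if d > 0 else 0.0
    return out


def simulate_coverage_table(source, depth: float = 30.0, seed: int = 0) -> CoverageTable:
    """Both sexes in one table (independent draws per sex)."""
    female = simulate_coverage(source, depth, "female", seed)
    male = simulate_coverage(source, depth, "male", seed)
    return CoverageTable(
        [
            CoverageRow(name, length, female[name], male[name])
            for name, length, _cls in _contig_list(source)
        ]
    )
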