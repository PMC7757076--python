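"""Sex-linkage calling from male/female read-depth ratios plus Z-homology,
and chimeric-scaffold flagging.

In a ZW system the female is the heterogametic sex: Z-linked contigs show
half coverage in the female and full coverage in the male; W-linked contigs
are female-specific (half female coverage, essentially no male reads); the
pseudoautosomal region and autosomes show full coverage in both sexes.
Read mapping itself is upstream; this module consumes a per-contig depth
table.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

import pandas as pd

from .config import AnalysisConfig
from .genome_io import GenomeSequences, Interval, merge_intervals, intervals_bp
from .local_align import NucleotideAligner, AlignParams

log = logging.getLogger(__name__)


@dataclass
class CoverageRow:
    contig: str
    length: int
    mean_depth_female: float
    mean_depth_male: float


class CoverageTable:
    def __init__(self, rows: list[CoverageRow]):
        names = [r.contig for r in rows]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names in coverage table")
        for r in rows:
            if r.mean_depth_female < 0 or r.mean_depth_male < 0:
                raise ValueError(f"negative depth for {r.contig}")
        self.rows = rows

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @classmethod
    def from_tsv(cls, path) -> "CoverageTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            [
                CoverageRow(
                    str(r["contig"]), int(r["length"]),
                    float(r["mean_depth_female"]), float(r["mean_depth_male"]),
                )
                for _, r in df.iterrows()
            ]
        )

    def to_tsv(self, path, provenance: str | None = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                for line in provenance.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("contig\tlength\tmean_depth_female\tmean_depth_male\n")
            for r in self.rows:
                fh.write(
                    f"{r.contig}\t{r.length}\t{r.mean_depth_female:.4f}\t{r.mean_depth_male:.4f}\n"
                )


@dataclass
class SexLinkageCall:
    contig: str
    call: str  # Z | W | PAR_or_Autosome | Unclassified
    f_ratio: float
    m_ratio: float
    z_homology: float | None = None


def homology_fraction(
    contig_seq: str,
    query_chromosome: GenomeSequences | NucleotideAligner,
    cfg: AnalysisConfig | None = None,
    chunk: int = 1000,
    params: AlignParams | None = None,
) -> float:
    """Fraction of a contig covered by merged filtered alignments to a query
    chromosome (e.g. a well-conserved Z of a related species).

    The contig is aligned in ``chunk``-bp pieces (whole-contig quadratic DP
    would not scale); covered query intervals of passing hits are merged and
    summed. Hits are filtered on identity and e-value only -- a per-chunk
    coverage filter would erase genuine partial homology in the chunk that
    straddles the homology boundary.
    """
    cfg = cfg or AnalysisConfig()
    if len(contig_seq) < 1000:
        raise ValueError("contig must be >= 1 kb")
    aligner = (
        query_chromosome
        if isinstance(query_chromosome, NucleotideAligner)
        else NucleotideAligner(query_chromosome, params)
    )
    covered = []
    for start in range(0, len(contig_seq), chunk):
        piece = contig_seq[start : start + chunk]
        if len(piece) < aligner.params.k:
            continue
        for h in aligner.align(piece):
            if h.identity < cfg.min_identity or h.evalue > cfg.max_evalue:
                continue
            covered.append(
                Interval("contig", start + h.query_span.start, start + h.query_span.end)
            )
    if not covered:
        return 0.0
    return intervals_bp(merge_intervals(covered)) / len(contig_seq)


def classify_sex_linkage(
    cov: CoverageTable,
    z_hom: dict[str, float] | None = None,
    cfg: AnalysisConfig | None = None,
    tolerance: float = 0.25,
    w_male_max: float = 0.1,
    length_floor: int = 10_000,
) -> list[SexLinkageCall]:
    """Call each contig Z, W, PAR_or_Autosome, or Unclassified.

    The autosomal baseline is the median depth over contigs that are not
    Z-homologous (z_hom <= the 60% rule) and pass the length floor, so sex
    chromosomes cannot contaminate the baseline. Calls (t = tolerance):

    * Z: z_hom > 0.60, or f_ratio in [0.5-t, 0.5+t] and m_ratio in [1-t, 1+t]
    * W: f_ratio in [0.5-t, 0.5+t] and m_ratio < w_male_max
    * PAR_or_Autosome: both ratios in [1-t, 1+t]
    * otherwise Unclassified

    The numeric windows are this package's declared defaults (the half- and
    zero-coverage expectations have no published numeric cutoffs).
    """
    cfg = cfg or AnalysisConfig()
    z_hom = z_hom or {}
    if len(cov) < 20:
        raise ValueError("need >= 20 contigs to estimate the autosomal median")
    baseline_rows = [
        r
        for r in cov
        if z_hom.get(r.contig, 0.0) <= cfg.z_homology_min and r.length >= length_floor
    ]
    if not baseline_rows:
        baseline_rows = list(cov)
    med_f = statistics.median(r.mean_depth_female for r in baseline_rows)
    med_m = statistics.median(r.mean_depth_male for r in baseline_rows)
    if med_f <= 0 or med_m <= 0:
        raise ValueError("degenerate autosomal median depth (0)")
    t = tolerance
    calls = []
    for r in cov:
        f_ratio = r.mean_depth_female / med_f
        m_ratio = r.mean_depth_male / med_m
        zh = z_hom.get(r.contig)
        half_f = 0.5 - t <= f_ratio <= 0.5 + t
        full_m = 1 - t <= m_ratio <= 1 + t
        full_f = 1 - t <= f_ratio <= 1 + t
        if (zh is not None and zh > cfg.z_homology_min) or (half_f and full_m):
            call = "Z"
        elif half_f and m_ratio < w_male_max:
            call = "W"
        elif full_f and full_m:
            call = "PAR_or_Autosome"
        else:
            call = "Unclassified"
        calls.append(SexLinkageCall(r.contig, call, f_ratio, m_ratio, zh))
    return calls


def flag_chimeric_scaffolds(
    scaffold_composition: dict[str, list[tuple[str, SexLinkageCall]]]
) -> list[str]:
    """Scaffolds composed of both sex-linked (Z or W) and autosomal
    (PAR_or_Autosome) contigs; Unclassified members are ignored."""
    flagged = []
    for scaffold, members in scaffold_composition.items():
        calls = {call.call for _contig, call in members}
        if calls & {"Z", "W"} and "PAR_or_Autosome" in calls:
            flagged.append(scaffold)
    return flagged
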