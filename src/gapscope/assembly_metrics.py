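"""Assembly census: gaps, contig decomposition, Nx statistics, missing
fraction relative to a reference, and the simplified LTR Assembly Index."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .config import AnalysisConfig
from .genome_io import (
    GenomeSequences,
    Interval,
    RepeatAnnotation,
    RepeatClass,
    intervals_bp,
    merge_intervals,
)

log = logging.getLogger(__name__)

_N_RUN = re.compile(r"N+")


@dataclass(frozen=True)
class GapRecord:
    """One maximal N-run in a scaffold."""

    scaffold: str
    interval: Interval
    length: int
    terminal: bool

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class AssemblyStats:
    scaffold_count: int
    contig_count: int
    scaffold_n50: int
    contig_n50: int
    total_len: int
    total_len_no_n: int
    gap_count: int
    gap_bp: int


def find_gaps(seqs: GenomeSequences, min_len: int = 1) -> list[GapRecord]:
    """All maximal N-runs of length >= min_len, sorted by (scaffold, start).

    ``terminal`` is set when the run touches position 0 or the scaffold end.
    Terminal runs are part of the gap census but are excluded from gap-cause
    analysis downstream (no flank on one side).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    gaps: list[GapRecord] = []
    for name, seq in seqs.items():
        for m in _N_RUN.finditer(seq):
            s, e = m.span()
            if e - s < min_len:
                continue
            gaps.append(
                GapRecord(
                    scaffold=name,
                    interval=Interval(name, s, e),
                    length=e - s,
                    terminal=(s == 0 or e == len(seq)),
                )
            )
    return gaps


def split_contigs(seqs: GenomeSequences, split_n: int = 25) -> list[Interval]:
    """Contigs: scaffold segments between N-runs of length >= split_n.

    N-runs shorter than split_n stay inside contigs (the assemblathon-style
    convention). All-N scaffolds contribute no contigs.
    """
    if split_n < 1:
        raise ValueError("split_n must be >= 1")
    contigs: list[Interval] = []
    for name, seq in seqs.items():
        pos = 0
        any_contig = False
        for m in _N_RUN.finditer(seq):
            s, e = m.span()
            if e - s >= split_n:
                if s > pos:
                    contigs.append(Interval(name, pos, s))
                    any_contig = True
                pos = e
        if pos < len(seq):
            contigs.append(Interval(name, pos, len(seq)))
            any_contig = True
        if not any_contig:
            log.warning("scaffold %s is all N; contributes no contigs", name)
    return contigs


def nx_statistic(lengths: list[int], x: float = 50.0) -> int:
    """Nx: smallest length L (descending order) whose cumulative sum reaches
    x% of the total."""
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    total = sum(lengths)
    threshold = x / 100.0 * total
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= threshold:
            return l
    return min(lengths)  # unreachable for valid x


def assembly_summary(seqs: GenomeSequences, cfg: AnalysisConfig | None = None) -> AssemblyStats:
    """Table-style assembly statistics.

    Scaffold stats use whole records; contig stats use split_contigs at
    ``cfg.contig_split_n``; the gap census counts every N-run (min_len=1,
    terminal runs included).
    """
    cfg = cfg or AnalysisConfig()
    if len(seqs) == 0:
        raise ValueError("empty assembly")
    scaffold_lengths = [len(s) for s in seqs.records.values()]
    contigs = split_contigs(seqs, cfg.contig_split_n)
    contig_lengths = [len(c) for c in contigs]
    gaps = find_gaps(seqs, min_len=1)
    gap_bp = sum(g.length for g in gaps)
    total_len = sum(scaffold_lengths)
    return AssemblyStats(
        scaffold_count=len(scaffold_lengths),
        contig_count=len(contig_lengths),
        scaffold_n50=nx_statistic(scaffold_lengths, 50),
        contig_n50=nx_statistic(contig_lengths, 50) if contig_lengths else 0,
        total_len=total_len,
        total_len_no_n=total_len - gap_bp,
        gap_count=len(gaps),
        gap_bp=gap_bp,
    )


def missing_fraction(draft: AssemblyStats, reference: AssemblyStats) -> float:
    """Percent of the reference missing from the draft, N bases excluded:
    100 * (1 - draft_size / reference_size). Negative when the draft is
    larger than the reference (reported as-is, with a warning)."""
    if reference.total_len_no_n <= 0:
        raise ValueError("reference has zero N-free length")
    value = 100.0 * (1.0 - draft.total_len_no_n / reference.total_len_no_n)
    if value < 0:
        log.warning("draft is larger than the reference (missing fraction %.2f%%)", value)
    return value


class UndefinedLAI(ValueError):
    """Raised when an annotation contains no LTR intervals."""


def lai_simplified(annot: RepeatAnnotation) -> float:
    """Simplified LTR Assembly Index: percent of LTR-retrotransposon bp that
    belongs to full-length elements, over all LTR bp (full-length plus
    fragments). Intervals are merged within each flag group before summing.

    The full-length flag must come from the annotation itself (the simulator
    emits it; for RepeatMasker output a family-length table is needed
    upstream) -- intact-LTR structure is not re-detected here.
    """
    ltr = annot.by_class(RepeatClass.LTR)
    if not ltr:
        raise UndefinedLAI("no LTR intervals in annotation")
    full = [r.interval for r in ltr if r.full_length]
    full_bp = intervals_bp(merge_intervals(full)) if full else 0
    all_bp = intervals_bp(merge_intervals([r.interval for r in ltr]))
    return 100.0 * full_bp / all_bp
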