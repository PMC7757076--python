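"""Multicopy-exon census and gene presence/absence classification.

The census generalizes a tandem-gene-family counting procedure: translated
searches of a panel of exon queries, hit-interval merging, and a strict
insertion-free length filter (hits must be *longer than* the threshold, so a
boundary-length hit is excluded). Gene presence uses chained translated hits
per scaffold/strand: 'complete' needs >= 95% of the protein aligned at
similarity > 90%, 'partial' is any weaker alignment, 'absent' is none.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .config import AnalysisConfig
from .genome_io import GenomeSequences, Interval
from .local_align import AlignmentHit, ProteinParams, TranslatedAligner

log = logging.getLogger(__name__)


@dataclass
class ExonQuerySet:
    """A named set of protein queries with the census length filters.

    ``query_alignment_length`` is on the nucleotide scale (e.g. 270 for a
    90-residue exon); ``min_hit_len`` is the strict nucleotide lower bound
    on the insertion-free hit length.
    """

    name: str
    query_alignment_length: int
    min_hit_len: int
    queries: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.min_hit_len < self.query_alignment_length:
            raise ValueError("min_hit_len must be below query_alignment_length")


@dataclass
class GenePresenceCall:
    gene_id: str
    status: str  # Complete | Partial | Absent
    aligned_fraction: float
    similarity: float


def merge_hits(hits: list[AlignmentHit]) -> list[Interval]:
    """Union of hit target spans per target sequence.

    Strictly overlapping intervals (>= 1 shared bp) are merged; abutting
    intervals are kept separate. Output sorted and disjoint.
    """
    by_target: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_target.setdefault(h.target_name, []).append(h)
    out: list[Interval] = []
    for name in sorted(by_target):
        spans = sorted((h.target_span.start, h.target_span.end) for h in by_target[name])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s < cur_e:  # strict overlap only; abutting not merged
                cur_e = max(cur_e, e)
            else:
                out.append(Interval(name, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(Interval(name, cur_s, cur_e))
    return out


def hit_query_length(hit: AlignmentHit) -> int:
    """Alignment columns in which the query has a residue (target insertions
    excluded), in nucleotides (3x residues for translated hits)."""
    if not hit.trace:
        raise ValueError("hit has no edit trace")
    cols = sum(length for op, length in hit.trace if op in ("M", "I"))
    return 3 * cols if hit.translated else cols


@dataclass
class CensusResult:
    name: str
    intervals: list[Interval]
    per_scaffold: Counter
    total: int
    table: pd.DataFrame


def exon_census(
    qset: ExonQuerySet,
    assembly: GenomeSequences | TranslatedAligner,
    cfg: AnalysisConfig | None = None,
    back_validate=None,
    params: ProteinParams | None = None,
) -> CensusResult:
    """Count merged translated-hit intervals for one exon query set.

    A hit passes iff its insertion-free length is strictly greater than
    ``qset.min_hit_len``. ``back_validate`` is an optional predicate applied
    to each merged interval before counting (hook for a reciprocal-best or
    database-backed screen; default off).
    """
    if not qset.queries:
        raise ValueError("empty query set")
    aligner = (
        assembly if isinstance(assembly, TranslatedAligner) else TranslatedAligner(assembly, params)
    )
    passing: list[AlignmentHit] = []
    for i, q in enumerate(qset.queries):
        for h in aligner.align(q, f"{qset.name}_q{i}"):
            if hit_query_length(h) > qset.min_hit_len:
                passing.append(h)
    merged = merge_hits(passing)
    if back_validate is not None:
        merged = [iv for iv in merged if back_validate(iv)]
    per_scaffold = Counter(iv.seq_name for iv in merged)
    table = pd.DataFrame(
        [
            {"scaffold": iv.seq_name, "start": iv.start, "end": iv.end, "set": qset.name}
            for iv in merged
        ],
        columns=["scaffold", "start", "end", "set"],
    )
    return CensusResult(qset.name, merged, per_scaffold, len(merged), table)


def _chain_hits(hits: list[AlignmentHit], max_intron: int) -> list[AlignmentHit]:
    """Greedy colinear chain on one scaffold/strand: add hits in descending
    score while they stay consistent in query/target order and within
    ``max_intron`` bp on the target."""
    chain: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda x: -x.raw_score):
        ok = True
        for c in chain:
            q_before = h.query_span.end <= c.query_span.start
            q_after = h.query_span.start >= c.query_span.end
            if not (q_before or q_after):
                ok = False
                break
            if h.strand == "+":
                t_consistent = (
                    h.target_span.end <= c.target_span.start
                    if q_before
                    else h.target_span.start >= c.target_span.end
                )
            else:
                t_consistent = (
                    h.target_span.start >= c.target_span.end
                    if q_before
                    else h.target_span.end <= c.target_span.start
                )
            if not t_consistent or h.target_span.distance(c.target_span) > max_intron:
                ok = False
                break
        if ok:
            chain.append(h)
    return chain


def gene_presence(
    protein_models: dict[str, str],
    assembly: GenomeSequences | TranslatedAligner,
    cfg: AnalysisConfig | None = None,
    max_intron: int = 20_000,
    params: ProteinParams | None = None,
) -> list[GenePresenceCall]:
    """Classify each gene model as Complete, Partial, or Absent.

    Hits are chained per scaffold/strand (greedy colinear chaining with a
    max intron span, a stand-in for splice-aware alignment); the chain with
    the highest summed score is scored. aligned_fraction is the covered
    query-residue fraction; similarity is the positive-scoring column
    fraction over aligned columns.
    """
    if not protein_models:
        raise ValueError("no gene models supplied")
    cfg = cfg or AnalysisConfig()
    aligner = (
        assembly if isinstance(assembly, TranslatedAligner) else TranslatedAligner(assembly, params)
    )
    calls: list[GenePresenceCall] = []
    for gene_id, seq in protein_models.items():
        hits = aligner.align(seq, gene_id)
        if not hits:
            calls.append(GenePresenceCall(gene_id, "Absent", 0.0, 0.0))
            continue
        groups: dict[tuple[str, str], list[AlignmentHit]] = {}
        for h in hits:
            groups.setdefault((h.target_name, h.strand), []).append(h)
        best_chain: list[AlignmentHit] = []
        best_score = -1
        for group in groups.values():
            chain = _chain_hits(group, max_intron)
            score = sum(h.raw_score for h in chain)
            if score > best_score:
                best_score = score
                best_chain = chain
        covered: set[int] = set()
        positives = 0
        aligned_cols = 0
        for h in best_chain:
            qpos = h.query_span.start
            for op, length in h.trace:  # only M columns count as aligned query residues
                if op == "M":
                    covered.update(range(qpos, qpos + length))
                    qpos += length
                elif op == "I":
                    qpos += length
            positives += h.positives
            aligned_cols += h.aligned_cols
        aligned_fraction = 100.0 * len(covered) / len(seq)
        similarity = 100.0 * positives / aligned_cols if aligned_cols else 0.0
        if aligned_fraction >= cfg.complete_gene_min_len and similarity > cfg.complete_gene_min_sim:
            status = "Complete"
        else:
            status = "Partial"
        calls.append(GenePresenceCall(gene_id, status, aligned_fraction, similarity))
    return calls
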