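"""Gap forensics: what repeats sit next to draft-assembly gaps (fragmentation
cause), and what the gaps correspond to on a curated reference (gap content,
via 500-bp flank liftover), plus per-class repeat recovery.

A draft gap is placed on the reference only when both flanks align uniquely,
on the same reference sequence, in a consistent orientation, within a sanity
span; everything else is NotScorable with an explicit reason.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .assembly_metrics import GapRecord, find_gaps
from .config import AnalysisConfig
from .genome_io import (
    GenomeSequences,
    Interval,
    RepeatAnnotation,
    RepeatClass,
)
from .local_align import AlignmentHit, NucleotideAligner, filter_hits

log = logging.getLogger(__name__)

CAUSE_LABELS = [c.name for c in RepeatClass] + ["Complex", "NoRepeat", "NotScorable"]

NOT_SCORABLE_REASONS = {
    "no_homology",
    "one_flank_only",
    "different_scaffolds",
    "maps_to_reference_gap",
    "terminal_gap",
    "ambiguous",
    "span_exceeded",
    "orientation_conflict",
}


@dataclass(frozen=True)
class GapCauseLabel:
    """A single cause label; ``reason`` is present iff label is NotScorable."""

    label: str
    reason: str | None = None

    def __post_init__(self):
        if self.label not in CAUSE_LABELS:
            raise ValueError(f"unknown label {self.label}")
        if (self.label == "NotScorable") != (self.reason is not None):
            raise ValueError("reason present iff label is NotScorable")
        if self.reason is not None and self.reason not in NOT_SCORABLE_REASONS:
            raise ValueError(f"unknown reason {self.reason}")

    @property
    def scorable(self) -> bool:
        return self.label != "NotScorable"


@dataclass
class GapPlacement:
    """A gap projected onto the reference between its two flank alignments.

    ``projected`` excludes the flank alignments themselves (it runs between
    their gap-proximal ends); when the flanks abut on the reference the
    projection is zero-length, ``projected`` is None and
    ``collapsed_to_zero`` is set.
    """

    gap: GapRecord
    left_hit: AlignmentHit
    right_hit: AlignmentHit
    projected: Interval | None
    orientation: str
    collapsed_to_zero: bool = False


class AnnotationIndex:
    """Interval-tree view of a RepeatAnnotation for overlap queries."""

    def __init__(self, annot: RepeatAnnotation):
        self.trees: dict[str, IntervalTree] = {}
        for rec in annot:
            iv = rec.interval
            self.trees.setdefault(iv.seq_name, IntervalTree()).addi(iv.start, iv.end, rec)

    def overlapping(self, iv: Interval):
        tree = self.trees.get(iv.seq_name)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]

    def near(self, iv: Interval, window: int):
        """Records overlapping iv extended by ``window`` bp on both sides
        (bedtools-window semantics: window=0 is direct overlap). Returns
        (distance, record) pairs, distance 0 for true overlap."""
        tree = self.trees.get(iv.seq_name)
        if tree is None:
            return []
        out = []
        for hit in tree.overlap(max(0, iv.start - window), iv.end + window):
            r = hit.data
            dist = max(0, iv.start - r.interval.end, r.interval.start - iv.end)
            out.append((dist, r))
        return out


def classify_adjacency(
    gaps: list[GapRecord],
    repeats: RepeatAnnotation | AnnotationIndex,
    cfg: AnalysisConfig | None = None,
) -> tuple[dict[GapRecord, GapCauseLabel], dict[GapRecord, Counter]]:
    """Label each gap by the repeat class adjacent to it.

    A repeat qualifies when it overlaps the gap extended by adjacency_window
    bp on each side (bedtools-window semantics; with window=0 this is plain
    overlap intersection).
    No qualifying repeat -> NoRepeat; one class -> that class; several
    classes -> the class of the nearest repeat, ties broken by larger
    overlap, then by the fixed RepeatClass order. The second return value is
    the full class multiset per gap, so alternative tabulations (e.g. a
    Complex-style one) remain recomputable.
    """
    cfg = cfg or AnalysisConfig()
    index = repeats if isinstance(repeats, AnnotationIndex) else AnnotationIndex(repeats)
    class_order = {c: i for i, c in enumerate(RepeatClass)}
    labels: dict[GapRecord, GapCauseLabel] = {}
    multisets: dict[GapRecord, Counter] = {}
    for gap in gaps:
        near = index.near(gap.interval, cfg.adjacency_window)
        multisets[gap] = Counter(r.repeat_class.name for _d, r in near)
        if not near:
            labels[gap] = GapCauseLabel("NoRepeat")
            continue

        def _key(item):
            dist, rec = item
            ov = max(
                0,
                min(gap.interval.end, rec.interval.end)
                - max(gap.interval.start, rec.interval.start),
            )
            return (dist, -ov, class_order[rec.repeat_class])

        best = min(near, key=_key)
        labels[gap] = GapCauseLabel(best[1].repeat_class.name)
    return labels, multisets


def extract_flanks(
    gap: GapRecord, seqs: GenomeSequences, cfg: AnalysisConfig | None = None
) -> tuple[str, str] | GapCauseLabel:
    """The flank_len bases on each side of a non-terminal gap.

    Returns a NotScorable skip-signal when fewer than flank_len bases exist
    on either side, or when a flank is more than 50% N (an adjacent-gap
    pathology).
    """
    cfg = cfg or AnalysisConfig()
    seq = seqs[gap.scaffold]
    L = cfg.flank_len
    if gap.terminal or gap.start < L or gap.end + L > len(seq):
        return GapCauseLabel("NotScorable", "terminal_gap")
    left = seq[gap.start - L : gap.start]
    right = seq[gap.end : gap.end + L]
    if left.count("N") > L / 2 or right.count("N") > L / 2:
        return GapCauseLabel("NotScorable", "terminal_gap")
    return left, right


def place_gap(
    gap: GapRecord,
    flanks: tuple[str, str],
    reference: GenomeSequences | NucleotideAligner,
    cfg: AnalysisConfig | None = None,
) -> GapPlacement | GapCauseLabel:
    """Align both flanks to the reference and project the gap between them.

    Passing a prebuilt :class:`NucleotideAligner` avoids re-indexing the
    reference for every gap.
    """
    cfg = cfg or AnalysisConfig()
    aligner = (
        reference if isinstance(reference, NucleotideAligner) else NucleotideAligner(reference)
    )
    left, right = flanks
    left_hits = filter_hits(aligner.align(left, "left_flank"), cfg)
    right_hits = filter_hits(aligner.align(right, "right_flank"), cfg)
    if not left_hits and not right_hits:
        return GapCauseLabel("NotScorable", "no_homology")
    if not left_hits or not right_hits:
        return GapCauseLabel("NotScorable", "one_flank_only")
    if len(left_hits) > 1 or len(right_hits) > 1:
        return GapCauseLabel("NotScorable", "ambiguous")
    lh, rh = left_hits[0], right_hits[0]
    if lh.target_name != rh.target_name:
        return GapCauseLabel("NotScorable", "different_scaffolds")
    if lh.strand != rh.strand:
        return GapCauseLabel("NotScorable", "orientation_conflict")
    orientation = lh.strand
    if orientation == "+":
        p_start, p_end = lh.target_span.end, rh.target_span.start
    else:
        p_start, p_end = rh.target_span.end, lh.target_span.start
    if p_start > p_end:
        return GapCauseLabel("NotScorable", "orientation_conflict")
    if p_end - p_start > cfg.max_projected_span:
        log.warning(
            "gap %s:%d-%d projected span %d exceeds max_projected_span",
            gap.scaffold, gap.start, gap.end, p_end - p_start,
        )
        return GapCauseLabel("NotScorable", "span_exceeded")
    if p_start == p_end:
        return GapPlacement(gap, lh, rh, None, orientation, collapsed_to_zero=True)
    return GapPlacement(
        gap, lh, rh, Interval(lh.target_name, p_start, p_end), orientation
    )


def classify_content(
    placement: GapPlacement,
    ref_repeats: RepeatAnnotation | AnnotationIndex,
    ref_gaps: list[GapRecord],
    cfg: AnalysisConfig | None = None,
) -> GapCauseLabel:
    """What the projected reference interval contains: one repeat class ->
    that class; several -> Complex; none -> NoRepeat; overlap with a
    reference gap -> NotScorable(maps_to_reference_gap)."""
    if placement.projected is None:  # flanks abut: collapsed to zero length
        return GapCauseLabel("NoRepeat")
    proj = placement.projected
    for g in ref_gaps:
        if g.interval.overlaps(proj):
            return GapCauseLabel("NotScorable", "maps_to_reference_gap")
    index = ref_repeats if isinstance(ref_repeats, AnnotationIndex) else AnnotationIndex(ref_repeats)
    classes = {r.repeat_class for r in index.overlapping(proj)}
    if not classes:
        return GapCauseLabel("NoRepeat")
    if len(classes) == 1:
        return GapCauseLabel(next(iter(classes)).name)
    return GapCauseLabel("Complex")


def repeat_recovery(
    draft_repeats: RepeatAnnotation, ref_repeats: RepeatAnnotation
) -> dict[RepeatClass, float | None]:
    """Per-class fraction of reference repeat bp recovered in the draft:
    (merged draft bp) / (merged reference bp). Classes absent from the
    reference are undefined (None); values above 1 are reported as-is with a
    warning (haplotype duplication)."""
    if len(draft_repeats) == 0 or len(ref_repeats) == 0:
        raise ValueError("both annotations must be nonempty")
    draft_bp = draft_repeats.class_bp()
    ref_bp = ref_repeats.class_bp()
    out: dict[RepeatClass, float | None] = {}
    for cls in RepeatClass:
        if cls not in ref_bp and cls not in draft_bp:
            continue
        if cls not in ref_bp:
            out[cls] = None
            continue
        frac = draft_bp.get(cls, 0) / ref_bp[cls]
        if frac > 1:
            log.warning("repeat recovery for %s is %.2f (> 1; duplication?)", cls.name, frac)
        out[cls] = frac
    return out


def tabulate_gap_causes(
    labels_adjacency: dict[GapRecord, GapCauseLabel],
    labels_content: dict[GapRecord, GapCauseLabel],
) -> dict[str, pd.DataFrame]:
    """Counts and proportions per cause label for both analyses.

    Proportions are reported on two bases: over all gaps, and over scorable
    gaps only (either denominator is defensible for summary plots, so
    both are emitted).
    """
    out = {}
    for name, labels in (("adjacency", labels_adjacency), ("content", labels_content)):
        counts = Counter(lbl.label for lbl in labels.values())
        n_all = sum(counts.values())
        n_scorable = n_all - counts.get("NotScorable", 0)
        rows = []
        for label in CAUSE_LABELS:
            c = counts.get(label, 0)
            if c == 0:
                continue
            rows.append(
                {
                    "label": label,
                    "count": c,
                    "prop_all": c / n_all if n_all else 0.0,
                    "prop_scorable": (
                        c / n_scorable if n_scorable and label != "NotScorable" else float("nan")
                    ),
                }
            )
        out[name] = pd.DataFrame(rows, columns=["label", "count", "prop_all", "prop_scorable"])
    return out


@dataclass
class GapAnalysisResult:
    gaps: list[GapRecord]
    adjacency: dict[GapRecord, GapCauseLabel]
    adjacency_multiset: dict[GapRecord, Counter]
    content: dict[GapRecord, GapCauseLabel]
    placements: dict[GapRecord, GapPlacement]
    collapsed_to_zero: int


def run_gap_analysis(
    draft: GenomeSequences,
    reference: GenomeSequences,
    draft_repeats: RepeatAnnotation,
    ref_repeats: RepeatAnnotation,
    cfg: AnalysisConfig | None = None,
) -> GapAnalysisResult:
    """Both gap analyses end to end on non-terminal gaps > the length filter."""
    cfg = cfg or AnalysisConfig()
    gaps = [g for g in find_gaps(draft, cfg.min_gap_len_analysis) if not g.terminal]
    adjacency, multiset = classify_adjacency(gaps, draft_repeats, cfg)
    aligner = NucleotideAligner(reference)
    ref_gaps = find_gaps(reference, min_len=1)
    ref_index = AnnotationIndex(ref_repeats)
    content: dict[GapRecord, GapCauseLabel] = {}
    placements: dict[GapRecord, GapPlacement] = {}
    collapsed = 0
    for gap in gaps:
        flanks = extract_flanks(gap, draft, cfg)
        if isinstance(flanks, GapCauseLabel):
            content[gap] = flanks
            continue
        placed = place_gap(gap, flanks, aligner, cfg)
        if isinstance(placed, GapCauseLabel):
            content[gap] = placed
            continue
        placements[gap] = placed
        if placed.collapsed_to_zero:
            collapsed += 1
        content[gap] = classify_content(placed, ref_index, ref_gaps, cfg)
    return GapAnalysisResult(gaps, adjacency, multiset, content, placements, collapsed)
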