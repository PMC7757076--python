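import numpy as np
import pytest

from gapscope.assembly_metrics import GapRecord, find_gaps
from gapscope.config import AnalysisConfig
from gapscope.gap_cause import (
    GapCauseLabel,
    GapPlacement,
    classify_adjacency,
    classify_content,
    extract_flanks,
    place_gap,
    repeat_recovery,
    tabulate_gap_causes,
)
from gapscope.genome_io import (
    GenomeSequences,
    Interval,
    RepeatAnnotation,
    RepeatClass,
    RepeatRecord,
)
from gapscope.local_align import revcomp

RNG = np.random.default_rng(31)


def rand_dna(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), n))


def _gap(seq_name, start, end):
    return GapRecord(seq_name, Interval(seq_name, start, end), end - start, False)


def _annot(*items):
    return RepeatAnnotation(
        [RepeatRecord(Interval("s", a, b), cls, "fam") for a, b, cls in items]
    )


class TestAdjacency:
    def test_repeat_within_window(self):
        labels, multi = classify_adjacency(
            [_gap("s", 1000, 1100)], _annot((850, 950, RepeatClass.LTR))
        )
        assert list(labels.values())[0] == GapCauseLabel("LTR")
        assert list(multi.values())[0] == {"LTR": 1}

    def test_strict_window_boundary(self):
        # repeat ending at 899: beyond the 100-bp window around the gap
        labels, _ = classify_adjacency(
            [_gap("s", 1000, 1100)], _annot((700, 899, RepeatClass.LTR))
        )
        assert list(labels.values())[0] == GapCauseLabel("NoRepeat")
        # a repeat reaching into the extended window qualifies
        labels, _ = classify_adjacency(
            [_gap("s", 1000, 1100)], _annot((700, 901, RepeatClass.LTR))
        )
        assert list(labels.values())[0] == GapCauseLabel("LTR")

    def test_nearest_class_wins(self):
        labels, multi = classify_adjacency(
            [_gap("s", 1000, 1100)],
            _annot((930, 990, RepeatClass.LTR), (880, 940, RepeatClass.Satellite)),
        )
        assert list(labels.values())[0] == GapCauseLabel("LTR")
        assert list(multi.values())[0] == {"LTR": 1, "Satellite": 1}

    def test_window_zero_equals_direct_overlap_oracle(self):
        rng = np.random.default_rng(8)
        cfg = AnalysisConfig(adjacency_window=1)
        cfg.adjacency_window = 0  # post-validation override: degenerate window
        classes = list(RepeatClass)
        for _ in range(300):
            gaps = [
                _gap("s", int(a), int(a + b))
                for a, b in zip(rng.integers(0, 5000, 5), rng.integers(20, 200, 5))
            ]
            items = [
                (int(a), int(a + b), classes[int(c)])
                for a, b, c in zip(
                    rng.integers(0, 5200, 12), rng.integers(10, 300, 12), rng.integers(0, 5, 12)
                )
            ]
            labels, multi = classify_adjacency(gaps, _annot(*items), cfg)
            for g in gaps:
                expect = {
                    cls.name
                    for a, b, cls in items
                    if a < g.interval.end and g.interval.start < b
                }
                assert set(multi[g].keys()) == expect
                if not expect:
                    assert labels[g] == GapCauseLabel("NoRepeat")
                else:
                    assert labels[g].label in expect

    def test_each_gap_gets_exactly_one_label(self):
        gaps = [_gap("s", 100, 200), _gap("s", 500, 600)]
        labels, _ = classify_adjacency(gaps, _annot((90, 120, RepeatClass.LINE)))
        assert len(labels) == len(gaps)


class TestExtractFlanks:
    def test_arithmetic(self):
        seq = rand_dna(2000)
        seqs = GenomeSequences({"s": seq[:1000] + "N" * 100 + seq[1000:1900]})
        gap = _gap("s", 1000, 1100)
        left, right = extract_flanks(gap, seqs)
        assert left == seq[500:1000]
        assert right == seq[1000:1500]

    def test_short_side_skips(self):
        seqs = GenomeSequences({"s": rand_dna(200) + "N" * 100 + rand_dna(800)})
        res = extract_flanks(_gap("s", 200, 300), seqs)
        assert isinstance(res, GapCauseLabel) and res.reason == "terminal_gap"

    def test_n_heavy_flank_skips(self):
        # second N-run covers 60% of the right flank
        seqs = GenomeSequences(
            {"s": rand_dna(1000) + "N" * 100 + rand_dna(200) + "N" * 300 + rand_dna(600)}
        )
        res = extract_flanks(_gap("s", 1000, 1100), seqs)
        assert isinstance(res, GapCauseLabel) and res.reason == "terminal_gap"


class TestPlaceGap:
    """Liftover fixtures built by deleting a region from a known reference."""

    def setup_method(self):
        rng = np.random.default_rng(12)
        self.chrA = rand_dna(4000, rng)
        self.chrB = rand_dna(4000, rng)

    def _draft_with_gap(self, removed=(1500, 1800)):
        s, e = removed
        draft_seq = self.chrA[:s] + "N" * 100 + self.chrA[e:]
        draft = GenomeSequences({"d": draft_seq})
        gap = find_gaps(draft, 1)[0]
        return draft, gap

    def test_identity_liftover_projects_exact_source(self):
        draft, gap = self._draft_with_gap()
        ref = GenomeSequences({"chrA": self.chrA, "chrB": self.chrB})
        flanks = extract_flanks(gap, draft)
        placed = place_gap(gap, flanks, ref)
        assert isinstance(placed, GapPlacement)
        assert placed.orientation == "+"
        assert (placed.projected.seq_name, placed.projected.start, placed.projected.end) == (
            "chrA", 1500, 1800,
        )

    def test_duplicated_left_flank_is_ambiguous(self):
        # the 500 bp left of the gap also exists verbatim on chrB
        dup = self.chrA[1000:1500]
        ref = GenomeSequences({"chrA": self.chrA, "chrB": self.chrB[:2000] + dup + self.chrB[2000:]})
        draft, gap = self._draft_with_gap()
        placed = place_gap(gap, extract_flanks(gap, draft), ref)
        assert placed == GapCauseLabel("NotScorable", "ambiguous")

    def test_flanks_on_different_reference_sequences(self):
        draft_seq = self.chrA[:1500] + "N" * 100 + self.chrB[2000:]
        draft = GenomeSequences({"d": draft_seq})
        gap = find_gaps(draft, 1)[0]
        ref = GenomeSequences({"chrA": self.chrA, "chrB": self.chrB})
        placed = place_gap(gap, extract_flanks(gap, draft), ref)
        assert placed == GapCauseLabel("NotScorable", "different_scaffolds")

    def test_strand_disagreement_is_orientation_conflict(self):
        draft_seq = self.chrA[:1500] + "N" * 100 + revcomp(self.chrA[1800:2400])
        draft = GenomeSequences({"d": draft_seq})
        gap = find_gaps(draft, 1)[0]
        ref = GenomeSequences({"chrA": self.chrA})
        placed = place_gap(gap, extract_flanks(gap, draft), ref)
        assert placed == GapCauseLabel("NotScorable", "orientation_conflict")

    def test_no_homology(self):
        draft_seq = rand_dna(1500) + "N" * 100 + rand_dna(1500)
        draft = GenomeSequences({"d": draft_seq})
        gap = find_gaps(draft, 1)[0]
        ref = GenomeSequences({"chrA": self.chrA})
        placed = place_gap(gap, extract_flanks(gap, draft), ref)
        assert placed == GapCauseLabel("NotScorable", "no_homology")

    def test_collapsed_to_zero_projection(self):
        draft_seq = self.chrA[:1500] + "N" * 100 + self.chrA[1500:]
        draft = GenomeSequences({"d": draft_seq})
        gap = find_gaps(draft, 1)[0]
        ref = GenomeSequences({"chrA": self.chrA})
        placed = place_gap(gap, extract_flanks(gap, draft), ref)
        assert isinstance(placed, GapPlacement)
        assert placed.collapsed_to_zero and placed.projected is None

    def test_span_exceeded(self):
        cfg = AnalysisConfig(max_projected_span=200)
        draft, gap = self._draft_with_gap((1500, 1800))
        ref = GenomeSequences({"chrA": self.chrA})
        placed = place_gap(gap, extract_flanks(gap, draft, cfg), ref, cfg)
        assert placed == GapCauseLabel("NotScorable", "span_exceeded")


class TestClassifyContent:
    def _placement(self, start, end):
        gap = _gap("d", 0, 100)
        return GapPlacement(gap, None, None, Interval("s", start, end), "+")

    def test_single_repeat_type(self):
        annot = _annot((120, 180, RepeatClass.Satellite))
        assert classify_content(self._placement(100, 200), annot, []) == GapCauseLabel("Satellite")

    def test_multiple_types_is_complex(self):
        annot = _annot((120, 140, RepeatClass.LTR), (150, 190, RepeatClass.SimpleRepeat))
        assert classify_content(self._placement(100, 200), annot, []) == GapCauseLabel("Complex")

    def test_reference_gap_overlap_not_scorable(self):
        annot = _annot((120, 180, RepeatClass.LTR))
        ref_gaps = [GapRecord("s", Interval("s", 150, 160), 10, False)]
        assert classify_content(self._placement(100, 200), annot, ref_gaps) == GapCauseLabel(
            "NotScorable", "maps_to_reference_gap"
        )

    def test_no_repeat_and_zero_length(self):
        annot = _annot((500, 600, RepeatClass.LTR))
        assert classify_content(self._placement(100, 200), annot, []) == GapCauseLabel("NoRepeat")
        collapsed = GapPlacement(_gap("d", 0, 100), None, None, None, "+", collapsed_to_zero=True)
        assert classify_content(collapsed, annot, []) == GapCauseLabel("NoRepeat")


class TestRepeatRecovery:
    def _annot_bp(self, cls, bp):
        return RepeatRecord(Interval("s", 0, bp), cls, "f")

    def test_ratio_and_duplication_flag(self):
        draft = RepeatAnnotation([self._annot_bp(RepeatClass.LTR, 80_000)])
        ref = RepeatAnnotation([self._annot_bp(RepeatClass.LTR, 100_000)])
        assert repeat_recovery(draft, ref)[RepeatClass.LTR] == pytest.approx(0.80)
        over = RepeatAnnotation([self._annot_bp(RepeatClass.LTR, 120_000)])
        assert repeat_recovery(over, ref)[RepeatClass.LTR] == pytest.approx(1.20)

    def test_class_absent_from_draft_is_zero_and_from_ref_undefined(self):
        draft = RepeatAnnotation([self._annot_bp(RepeatClass.LINE, 10_000)])
        ref = RepeatAnnotation([self._annot_bp(RepeatClass.LTR, 100_000)])
        rec = repeat_recovery(draft, ref)
        assert rec[RepeatClass.LTR] == 0.0
        assert rec[RepeatClass.LINE] is None


class TestTabulate:
    def test_proportions_on_both_bases(self):
        labels = {}
        for i in range(4):
            labels[_gap("s", i * 1000, i * 1000 + 100)] = GapCauseLabel("LTR")
        for i in range(4, 7):
            labels[_gap("s", i * 1000, i * 1000 + 100)] = GapCauseLabel("SimpleRepeat")
        for i in range(7, 10):
            labels[_gap("s", i * 1000, i * 1000 + 100)] = GapCauseLabel("NotScorable", "no_homology")
        tables = tabulate_gap_causes(labels, labels)
        df = tables["adjacency"].set_index("label")
        assert df.loc["LTR", "prop_all"] == pytest.approx(0.4)
        assert df.loc["SimpleRepeat", "prop_all"] == pytest.approx(0.3)
        assert df.loc["LTR", "prop_scorable"] == pytest.approx(4 / 7)
        assert df.loc["SimpleRepeat", "prop_scorable"] == pytest.approx(3 / 7)
        assert int(df["count"].sum()) == 10

    def test_zero_gaps_gives_empty_tables(self):
        tables = tabulate_gap_causes({}, {})
        assert len(tables["adjacency"]) == 0 and len(tables["content"]) == 0


def test_label_invariants():
    with pytest.raises(ValueError):
        GapCauseLabel("NotScorable")  # reason required
    with pytest.raises(ValueError):
        GapCauseLabel("LTR", "no_homology")  # reason forbidden
    with pytest.raises(ValueError):
        GapCauseLabel("Banana")
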