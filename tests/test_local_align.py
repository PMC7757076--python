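import numpy as np
import pytest
from Bio import Align

from gapscope.config import AnalysisConfig
from gapscope.genome_io import GenomeSequences
from gapscope.homology_census import hit_query_length
from gapscope.local_align import (
    align_local,
    encode_nt,
    filter_hits,
    read_tabular_hits,
    revcomp,
    smith_waterman,
    translated_search,
    _nt_matrix,
)

RNG = np.random.default_rng(2024)


def rand_dna(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), n))


def sw_oracle_nt():
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -7  # first gap base costs open(5) + extend(2)
    a.extend_gap_score = -2
    return a


class TestSmithWaterman:
    def test_score_matches_independent_oracle_with_planted_homology(self):
        oracle = sw_oracle_nt()
        sub = _nt_matrix(2, -3)
        rng = np.random.default_rng(5)
        for trial in range(60):
            n1 = int(rng.integers(60, 800))
            a = rand_dna(n1, rng)
            b = rand_dna(int(rng.integers(60, 800)), rng)
            if trial % 2 == 0:  # plant a mutated shared segment
                seg = list(a[10 : 10 + min(200, n1 - 10)])
                for i in rng.choice(len(seg), size=len(seg) // 20, replace=False):
                    seg[i] = "ACGT"[rng.integers(4)]
                b = b[:30] + "".join(seg) + b[30:]
            res = smith_waterman(encode_nt(a), encode_nt(b), sub, 5, 2)
            mine = res["score"] if res else 0
            if mine:
                assert mine == int(oracle.score(a, b))

    def test_trace_is_consistent_with_counts(self):
        sub = _nt_matrix(2, -3)
        a, b = "ACGTACGTAC", "ACGTTACGTAC"
        res = smith_waterman(encode_nt(a), encode_nt(b), sub, 5, 2)
        m = sum(l for op, l in res["trace"] if op == "M")
        assert m == res["matches"] + res["mismatches"] == res["aligned_cols"]
        assert res["score"] > 0


class TestAlignLocal:
    def setup_method(self):
        rng = np.random.default_rng(99)
        self.target = rand_dna(20000, rng)
        self.targets = GenomeSequences({"t": self.target})

    def test_exact_substring_full_identity(self):
        hits = align_local(self.target[5000:5500], self.targets)
        top = hits[0]
        assert top.identity == 100.0
        assert top.query_coverage == 100.0
        assert top.strand == "+"
        assert (top.target_span.start, top.target_span.end) == (5000, 5500)

    def test_reverse_complement_flips_strand_keeps_span_and_score(self):
        q = self.target[5000:5500]
        fwd = align_local(q, self.targets)[0]
        rev = align_local(revcomp(q), self.targets)[0]
        assert rev.strand == "-"
        assert (rev.target_span.start, rev.target_span.end) == (5000, 5500)
        assert rev.raw_score == fwd.raw_score

    def test_eleven_interior_mismatches_fail_the_98_filter(self):
        rng = np.random.default_rng(4)
        q = list(self.target[8000:8500])
        pos = rng.choice(np.arange(5, 495), size=11, replace=False)
        for i in pos:
            old = q[i]
            q[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[old]
        hits = align_local("".join(q), self.targets)
        top = hits[0]
        assert top.identity == pytest.approx(100 * 489 / 500)
        assert filter_hits([top], AnalysisConfig()) == []

    def test_query_shorter_than_seed_returns_empty_with_warning(self, caplog):
        assert align_local("ACGTACGTAC", self.targets) == []


class TestFilterHits:
    def _mk(self, identity, cov, ev):
        h = align_local("A" * 20, GenomeSequences({"t": "A" * 100}))  # placeholder
        # build a hit manually instead: cheaper and explicit
        from gapscope.genome_io import Interval
        from gapscope.local_align import AlignmentHit

        return AlignmentHit(
            "q", "t", Interval("q", 0, 450), Interval("t", 0, 450, "+"), "+",
            matches=440, mismatches=10, gap_opens=0, aligned_cols=450,
            identity=identity, query_coverage=cov, raw_score=800, evalue=ev,
        )

    def test_boundaries_inclusive(self):
        cfg = AnalysisConfig()
        kept = filter_hits([self._mk(98.0, 90.0, 1e-21)], cfg)
        assert len(kept) == 1

    def test_identity_below_threshold_dropped(self):
        assert filter_hits([self._mk(97.9, 99.0, 0.0)], AnalysisConfig()) == []

    def test_empty_and_idempotent_and_order_preserving(self):
        cfg = AnalysisConfig()
        assert filter_hits([], cfg) == []
        hits = [self._mk(99, 95, 1e-30), self._mk(98, 90, 1e-25)]
        once = filter_hits(hits, cfg)
        assert filter_hits(once, cfg) == once == hits


class TestTranslatedSearch:
    def setup_method(self):
        rng = np.random.default_rng(17)
        self.codons = []
        stops = {"TAA", "TAG", "TGA"}
        while len(self.codons) < 90:
            c = rand_dna(3, rng)
            if c not in stops:
                self.codons.append(c)
        self.exon = "".join(self.codons)
        from Bio.Seq import Seq

        self.protein = str(Seq(self.exon).translate())
        self.left = rand_dna(600, rng)
        self.right = rand_dna(600, rng)

    def test_planted_exon_found_at_full_identity(self):
        targets = GenomeSequences({"t": self.left + "TAA" + self.exon + "TAA" + self.right})
        hits = translated_search(self.protein, targets)
        top = hits[0]
        assert top.identity == 100.0
        assert top.strand == "+"
        assert (top.target_span.start, top.target_span.end) == (603, 603 + 270)

    def test_minus_strand_exon_same_hit_flipped(self):
        cassette = "TAA" + self.exon + "TAA"
        targets = GenomeSequences({"t": self.left + revcomp(cassette) + self.right})
        top = translated_search(self.protein, targets)[0]
        assert top.strand == "-"
        assert top.identity == 100.0
        assert (top.target_span.start, top.target_span.end) == (603, 603 + 270)

    def test_in_frame_insertion_keeps_query_residue_count(self):
        # 9-bp (3-codon) insertion in the target mid-exon
        ins = "GCTGCAGCC"
        target_exon = self.exon[: 45 * 3] + ins + self.exon[45 * 3 :]
        targets = GenomeSequences({"t": self.left + "TAA" + target_exon + "TAA" + self.right})
        hits = translated_search(self.protein, targets)
        top = hits[0]
        assert top.gap_opens >= 1
        assert hit_query_length(top) == 270  # target insertion excluded

    def test_non_amino_acid_query_is_error(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            translated_search("MKV1LLL" + "A" * 20, GenomeSequences({"t": "ACGT" * 100}))


def test_tabular_import_maps_coordinates_and_strand(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text(
        "q1\ts1\t98.00\t500\t10\t0\t1\t500\t1001\t1500\t1e-200\t900\n"
        "q1\ts2\t95.00\t100\t5\t1\t50\t149\t2000\t1901\t1e-20\t150\n"
    )
    hits = read_tabular_hits(p, query_lengths={"q1": 500})
    a, b = hits
    assert (a.query_span.start, a.query_span.end) == (0, 500)
    assert (a.target_span.start, a.target_span.end) == (1000, 1500)
    assert a.strand == "+" and b.strand == "-"
    assert (b.target_span.start, b.target_span.end) == (1900, 2000)
    assert a.query_coverage == pytest.approx(100.0)
    assert b.identity == pytest.approx(95.0)
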