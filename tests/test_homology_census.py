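import numpy as np
import pytest
from Bio.Seq import Seq

from gapscope.config import AnalysisConfig
from gapscope.genome_io import GenomeSequences, Interval
from gapscope.homology_census import (
    ExonQuerySet,
    exon_census,
    gene_presence,
    hit_query_length,
    merge_hits,
)
from gapscope.local_align import AlignmentHit

RNG = np.random.default_rng(77)
STOPS = {"TAA", "TAG", "TGA"}


def rand_dna(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), n))


def rand_codons(n, rng=RNG):
    out = []
    while len(out) < n:
        c = rand_dna(3, rng)
        if c not in STOPS:
            out.append(c)
    return "".join(out)


def _hit(target, start, end, trace=None, translated=False, qlen=100):
    return AlignmentHit(
        "q", target, Interval("q", 0, qlen), Interval(target, start, end, "+"), "+",
        matches=end - start, mismatches=0, gap_opens=0, aligned_cols=end - start,
        identity=100.0, query_coverage=100.0, raw_score=2 * (end - start), evalue=0.0,
        trace=[("M", end - start)] if trace is None else trace, translated=translated,
    )


class TestMergeHits:
    def test_overlap_union(self):
        merged = merge_hits([_hit("t", 100, 300), _hit("t", 250, 400)])
        assert [(m.start, m.end) for m in merged] == [(100, 400)]

    def test_abutting_not_merged(self):
        merged = merge_hits([_hit("t", 100, 200), _hit("t", 200, 300)])
        assert [(m.start, m.end) for m in merged] == [(100, 200), (200, 300)]

    def test_different_scaffolds_kept_apart(self):
        merged = merge_hits([_hit("a", 0, 50), _hit("b", 0, 50)])
        assert [(m.seq_name, m.start, m.end) for m in merged] == [("a", 0, 50), ("b", 0, 50)]

    def test_idempotent_and_bp_bounded(self):
        hits = [_hit("t", 10, 60), _hit("t", 40, 90), _hit("t", 95, 120)]
        merged = merge_hits(hits)
        again = merge_hits([_hit(m.seq_name, m.start, m.end) for m in merged])
        assert [(m.start, m.end) for m in again] == [(m.start, m.end) for m in merged]
        assert sum(len(m) for m in merged) <= sum(
            h.target_span.end - h.target_span.start for h in hits
        )


class TestHitQueryLength:
    def test_translated_with_target_insertion(self):
        # 90 query residues aligned, one 3-residue target insertion (D op)
        trace = [("M", 45), ("D", 3), ("M", 45)]
        assert hit_query_length(_hit("t", 0, 279, trace, translated=True)) == 270

    def test_ungapped_translated(self):
        assert hit_query_length(_hit("t", 0, 240, [("M", 80)], translated=True)) == 240

    def test_query_insertion_counts_nucleotide_scale(self):
        trace = [("M", 40), ("I", 10), ("M", 30)]
        assert hit_query_length(_hit("t", 0, 210, trace, translated=False)) == 80

    def test_missing_trace_is_error(self):
        with pytest.raises(ValueError, match="trace"):
            hit_query_length(_hit("t", 0, 100, trace=[]))


class TestExonCensus:
    def _mini_genome(self, rng):
        """Three diverged full paralogs plus one copy truncated to exactly 80
        codons (insertion-free hit length 240, the strict census boundary)."""
        codons = rand_codons(90, rng)
        protein = str(Seq(codons).translate())
        copies = []
        for _ in range(3):
            c = list(codons)
            for ci in rng.choice(90, size=5, replace=False):
                block = c[3 * ci : 3 * ci + 3]
                cand = rand_dna(3, rng)
                if cand not in STOPS:
                    c[3 * ci : 3 * ci + 3] = cand
            copies.append("".join(c))
        trunc = codons[: 80 * 3]
        # spacers long enough that the six-frame search takes the seeded
        # path, which reports every copy rather than one best per frame
        parts = [rand_dna(2500, rng)]
        for cp in copies + [trunc]:
            parts.append("TAA" + cp + "TAA")
            parts.append(rand_dna(2500, rng))
        return GenomeSequences({"chr": "".join(parts)}), protein

    def test_census_counts_full_paralogs_and_drops_boundary_hit(self):
        rng = np.random.default_rng(3)
        genome, protein = self._mini_genome(rng)
        qset = ExonQuerySet("exon2", 270, 240, [protein])
        res = exon_census(qset, genome, AnalysisConfig())
        assert res.total == 3  # the 240-nt copy is excluded by strict >
        assert res.per_scaffold["chr"] == 3

    def test_relaxed_threshold_recovers_the_truncated_copy(self):
        rng = np.random.default_rng(3)
        genome, protein = self._mini_genome(rng)
        qset = ExonQuerySet("exon2", 270, 239, [protein])
        res = exon_census(qset, genome, AnalysisConfig())
        assert res.total == 4

    def test_back_validation_hook_filters(self):
        rng = np.random.default_rng(3)
        genome, protein = self._mini_genome(rng)
        qset = ExonQuerySet("exon2", 270, 240, [protein])
        res = exon_census(qset, genome, AnalysisConfig(), back_validate=lambda iv: iv.start > 6000)
        assert res.total < 3


class TestGenePresence:
    def test_complete_partial_absent(self):
        rng = np.random.default_rng(9)
        codons = rand_codons(150, rng)
        protein = str(Seq(codons).translate())
        intact = rand_dna(600, rng) + "TAA" + codons + "TAA" + rand_dna(600, rng)
        # split assembly: 5' third, then a gap, missing middle, then 3' third
        left = codons[: 50 * 3]
        right = codons[100 * 3 :]
        split = (
            rand_dna(600, rng) + "TAA" + left + "N" * 100 + right + "TAA" + rand_dna(600, rng)
        )
        assembly = GenomeSequences({"intact": intact, "split": split})
        calls = gene_presence({"gene": protein}, GenomeSequences({"intact": intact}))
        assert calls[0].status == "Complete"
        assert calls[0].aligned_fraction == pytest.approx(100.0)

        calls = gene_presence({"gene": protein}, GenomeSequences({"split": split}))
        assert calls[0].status == "Partial"
        assert calls[0].aligned_fraction < 95.0

        calls = gene_presence({"gene": protein}, GenomeSequences({"bg": rand_dna(3000, rng)}))
        assert calls[0].status == "Absent"
        assert calls[0].aligned_fraction == 0.0

    def test_gene_presence_on_truth_genome_all_complete(self, truth1):
        models = {g: info["protein"] for g, info in truth1.genes.items()}
        calls = gene_presence(models, truth1.genome)
        assert all(c.status == "Complete" for c in calls)
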