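import pytest

from gapscope.genome_io import RepeatClass
from gapscope.synthetic_data import (
    SimulationConfig,
    build_truth_genome,
    derive_draft,
    simulate_coverage,
)

#: a desk-scale config for fast structural checks
SMALL = dict(
    n_macro=2, n_micro=2, macro_len=120_000, micro_len=60_000,
    z_len=60_000, w_len=80_000, par_len=20_000,
    n_breaks=40, n_background_breaks=4, n_genes=4,
)


def small_cfg(**over):
    return SimulationConfig(**{**SMALL, **over})


class TestTruthGenome:
    def test_deterministic_under_seed(self):
        t1 = build_truth_genome(small_cfg(seed=5))
        t2 = build_truth_genome(small_cfg(seed=5))
        assert t1.genome.records == t2.genome.records
        t3 = build_truth_genome(small_cfg(seed=6))
        assert t1.genome.records != t3.genome.records

    def test_w_repeat_density_near_target(self):
        truth = build_truth_genome(small_cfg(seed=1))
        w_bp = sum(
            len(r.interval) for r in truth.repeats if r.interval.seq_name == "chrW"
        )
        density = 100 * w_bp / truth.config.w_len
        assert 68 <= density <= 72

    def test_micro_gc_matches_config(self):
        truth = build_truth_genome(small_cfg(seed=1))
        for name, cls in truth.chromosome_table.items():
            if cls != "micro":
                continue
            seq = truth.genome[name]
            gc = 100 * (seq.count("G") + seq.count("C")) / len(seq)
            assert 57 <= gc <= 63

    def test_every_annotated_repeat_matches_its_interval(self):
        truth = build_truth_genome(small_cfg(seed=2))
        for ft in truth.features:
            if ft.kind == "repeat":
                assert truth.genome[ft.chrom][ft.start : ft.end] == ft.seq

    def test_ltr_terminal_repeats_nearly_identical(self):
        truth = build_truth_genome(small_cfg(seed=1))
        tr = truth.config.ltr_terminal
        for ft in truth.features:
            if ft.kind == "repeat" and ft.full_length and ft.repeat_class is RepeatClass.LTR:
                seq = ft.seq
                left, right = seq[:tr], seq[-tr:]
                ident = sum(a == b for a, b in zip(left, right)) / tr
                assert ident >= 0.99

    def test_infeasible_mix_is_an_error_before_generation(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_truth_genome(small_cfg(micro_len=8000, seed=1))

    def test_exon_paralog_count_and_cluster_location(self):
        truth = build_truth_genome(small_cfg(seed=1))
        assert len(truth.exon_paralogs) == truth.config.n_exon_paralogs
        assert {iv.seq_name for iv, _s, _p in truth.exon_paralogs} == {"micro1"}


class TestDeriveDraft:
    def test_reconstruction_exact_without_mutation(self):
        truth = build_truth_genome(small_cfg(seed=3))
        dt = derive_draft(truth)
        for scaf, ds, de, chrom, ts, te, strand in dt.contig_map:
            assert strand == "+"
            assert dt.draft[scaf][ds:de] == truth.genome[chrom][ts:te]

    def test_gap_truth_matches_actual_n_runs(self):
        from gapscope.assembly_metrics import find_gaps

        truth = build_truth_genome(small_cfg(seed=3))
        dt = derive_draft(truth)
        gaps = {(g.scaffold, g.start, g.end) for g in find_gaps(dt.draft, 1)}
        for gt in dt.gap_truth:
            assert (gt.scaffold, gt.start, gt.end) in gaps
        assert len(gaps) == len(dt.gap_truth)

    def test_forced_break_bias_on_satellites(self):
        bias = {c.name: 0.0 for c in RepeatClass} | {"Satellite": 1.0, "Complex": 0.0}
        truth = build_truth_genome(small_cfg(seed=4, break_bias=bias, n_breaks=10,
                                             n_background_breaks=0))
        dt = derive_draft(truth)
        causes = {g.cause for g in dt.gap_truth if not g.tag}
        assert causes == {"Satellite"}

    def test_planted_special_cases_present(self):
        truth = build_truth_genome(small_cfg(seed=3))
        dt = derive_draft(truth)
        tags = {g.tag for g in dt.gap_truth if g.tag}
        assert {"dup_ambiguous", "gene_split", "gene_absent", "chimera_junction"} <= tags

    def test_chimeric_scaffold_mixes_chromosome_classes(self):
        truth = build_truth_genome(small_cfg(seed=3))
        dt = derive_draft(truth)
        classes = {name: cls for name, _l, cls in dt.contig_table}
        w_members = {classes[c] for c in dt.scaffold_composition["scaf_chrW"]}
        assert "W" in w_members and "macro" in w_members

    def test_mutation_rate_perturbs_draft_only(self):
        t0 = build_truth_genome(small_cfg(seed=3, mutation_rate=0.01))
        t1 = build_truth_genome(small_cfg(seed=3))
        assert t0.genome.records == t1.genome.records
        d0 = derive_draft(t0)
        d1 = derive_draft(t1)
        assert d0.draft.records != d1.draft.records


class TestCoverage:
    def test_ploidy_expectations(self):
        truth = build_truth_genome(small_cfg(seed=1))
        dt = derive_draft(truth)
        female = simulate_coverage(dt, 30.0, "female", seed=1)
        male = simulate_coverage(dt, 30.0, "male", seed=1)
        for name, length, cls in dt.contig_table:
            if length < 10_000:
                continue
            if cls in ("macro", "micro", "PAR-segment"):
                assert abs(female[name] - 30) < 3 and abs(male[name] - 30) < 3
            elif cls == "Z":
                assert abs(female[name] - 15) < 3 and abs(male[name] - 30) < 3
            elif cls == "W":
                assert abs(female[name] - 15) < 3 and male[name] == 0.0

    def test_invalid_args(self):
        truth = build_truth_genome(small_cfg(seed=1))
        with pytest.raises(ValueError):
            simulate_coverage(truth, -1.0, "female", 1)
        with pytest.raises(ValueError):
            simulate_coverage(truth, 30.0, "neuter", 1)
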