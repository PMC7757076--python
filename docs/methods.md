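# Methods

## Coordinate conventions and data model

All internal coordinates are 0-based half-open; the only conversions happen
inside readers and writers (RepeatMasker `.out` is 1-based inclusive with
`C` for the minus strand; BED needs none). Sequences are normalized to
uppercase {A,C,G,T,N}; IUPAC ambiguity codes other than N are folded to N
with a logged count rather than rejected, because real assembly pipelines
emit them sporadically and silently. Repeat class/family strings map to ten
canonical classes (LINE, SINE, LTR, DNA, Satellite, SimpleRepeat,
LowComplexity, rRNA, Unknown, Other) through an editable mapping table
keyed on the text before the first `/`; unmatched strings fall back to
Unknown.

## Assembly statistics

Gaps are maximal N-runs; the gap census counts every run including terminal
ones (a terminal run is still missing sequence), but gap-cause analysis
excludes terminal runs because it needs a flank on both sides. Contigs are
scaffold segments between N-runs of at least `contig_split_n` bp
(default 25, the assemblathon-script convention; shorter runs stay inside
contigs). Nx is the smallest length in the descending-sorted list whose
cumulative sum reaches x% of the total. The missing fraction relative to a
reference is `100 × (1 − draft/reference)` over N-free lengths and is
deliberately not clamped: a negative value (draft larger than reference,
e.g. haplotype duplication) is reported with a warning rather than hidden.

The simplified LTR Assembly Index is the percent of LTR-retrotransposon bp
belonging to elements flagged full-length, over all LTR bp (intervals
merged within each flag group). The full-length flag must come from the
annotation: the simulator emits it directly, and for RepeatMasker input a
family-length table is required upstream. Intact-LTR structure detection
(terminal-repeat pairing, target-site duplications) is intentionally out of
scope; this index is a completeness proxy, not a re-implementation of the
full LAI algorithm, and an annotation with no LTR rows yields a distinct
"undefined" signal rather than 0.

## The local aligner

Liftover and censusing need thousands of local alignments against a
multi-megabase reference with no external binaries, so the aligner is a
seed-and-extend design: exact k-mer seeds (k = 15 nucleotide, k = 5
protein) located through a sorted-array index, clustered along the target
(clusters closer than 400 bp merge; singleton clusters are discarded as
noise), and each cluster window — padded by one query length — is resolved
with a full affine-gap Smith–Waterman restricted to that window. Targets
shorter than 5 kb skip seeding entirely and get the full dynamic program,
so on test-scale sequences the reported score *is* the Smith–Waterman
optimum, which is how the test suite checks it against an independent
implementation (Biopython's `PairwiseAligner`).

The DP is exact and row-vectorized. With `Hpre = max(0, diagonal,
vertical)`, the horizontal gap state satisfies

    E[i][j] = max_{j' < j} Hpre[i][j'] − open − ext·(j − j')

because re-opening a horizontal gap from a cell whose value came from E is
always dominated by extending the existing gap. The right-hand side is a
running prefix maximum, so each row costs a handful of numpy operations.
Traceback prefers diagonal over horizontal over vertical, and gap extension
over re-opening; ties therefore resolve deterministically.

Scores: nucleotide match +2 / mismatch −3 (N matches nothing, not even N),
gap open 5 / extend 2 (a gap of length L costs 5 + 2L); protein BLOSUM62
with gap open 11 / extend 1. Stop codons and X (the translation of N runs)
carry a prohibitive −1000, so translated alignments never cross a stop or
an assembly gap — frames effectively break there, and split genes produce
two chained hits instead of one gap-riddled hit. E-values use the
Karlin–Altschul form `K·m·n·e^(−λS)` with fixed constants (nucleotide
K = 0.41, λ = 0.625; protein K = 0.041, λ = 0.267). These are declared
defaults for the scoring schemes above, not fitted values; they differ from
BLAST's numerically but agree within the order of magnitude, which is far
from the 1e-20 decision boundary for any real 500-bp flank hit (an exact
flank scores ~1000, e-value below 1e-250).

Hit filters are boundary-inclusive (identity ≥ 98, coverage ≥ 90,
e-value ≤ 1e-20), matching `-perc_identity`-style semantics. Overlapping
hits on the same target and strand keep only the higher-scoring one; final
order is ascending e-value, then target coordinate, then `+` before `-`.
One caveat of window-restricted extension: two near-identical copies closer
than about a window width on the *same* target merge into one window and
yield one hit, so tandem duplications at sub-kilobase spacing cannot
trigger the ambiguity rule. Dispersed and inter-chromosomal duplications —
the case the liftover must detect — always produce separate hits.

## Gap-cause classification

*Adjacency*: a repeat qualifies for a gap when it overlaps the gap extended
by `adjacency_window` bp (default 100) on each side — exact
bedtools-window semantics, so window = 0 degenerates to plain overlap
intersection (a property the tests exercise against a brute-force oracle;
note that an interval *abutting* the window edge does not qualify). A gap
with qualifying repeats of several classes takes the class of the nearest
one, ties broken by larger overlap, then by the fixed class order; the full
class multiset is preserved in a secondary output so alternative
tabulations (e.g. a Complex-style one) remain recomputable.

*Liftover*: flanks of `flank_len` = 500 bp are taken immediately left and
right of the gap; gaps without a full flank on either side, or with a flank
more than half N (adjacent-gap pathology), are skipped as NotScorable.
"Unique" means exactly one filter-surviving hit per flank. The projected
interval runs between the gap-proximal ends of the two flank hits and
excludes the flank alignments themselves; when the flanks abut on the
reference the projection is zero-length, which is classified NoRepeat and
counted separately as collapsed-to-zero. A projected span above
`max_projected_span` (default 100 kb) is rejected as span_exceeded — a
guard against paralogous flank pairings; the bound is this package's
choice, surfaced in output whenever it fires. Content classification is
strict overlap of the projected interval with reference repeats (one class,
Complex, or NoRepeat), with overlap of any reference N-run taking
precedence as maps_to_reference_gap.

Proportions are tabulated on two denominators — all gaps and scorable gaps
— because either basis is defensible and the choice changes the numbers.

## Composition scans

GC windows are consecutive, non-overlapping, `gc_window` = 1000 bp;
the final partial window is kept when it is at least half a window
(discarding it would systematically drop microchromosome tails on small
genomes); windows more than half N are excluded and counted; GC is
computed over unambiguous bases; thresholds (58.8, alternative 70) are
strict `>`.

The G4 scan is the canonical quadruplex motif `G{3,}(N{1,7}G{3,}){3,}`
(loop cap 7, configurable 1–12), applied greedily left to right; the minus
strand is scanned as the same pattern on the reverse complement with
coordinates mapped back, which makes strand symmetry exact by construction.
Motifs are non-overlapping within each strand; a G-motif and a C-motif may
rarely overlap each other and both are kept. This deliberately replaces a
machine-learned quadruplex score whose model is not reproducible here;
output columns are labelled `g4_canonical` so the two can never be
conflated, and no numeric agreement with score-filtered counts is implied.

## Homology census and gene presence

Census hits pass if their insertion-free length — alignment columns in
which the query has a residue, ×3 for translated hits — is *strictly*
greater than `min_hit_len` (240 nt for a 270-nt query set, 195 for 220):
a boundary-length hit is excluded. Merging is per target sequence and
strictly-overlapping only; abutting intervals stay separate, so adjacent
paralogs are not fused. A back-validation hook (a caller-supplied predicate
per merged interval) preserves the pipeline position of database-backed
screening without pretending to reproduce it; it defaults to off.

Gene presence chains translated hits per scaffold/strand greedily by
descending score under colinearity and a 20-kb maximum target gap — a
stand-in for splice-aware alignment that is exact for the single-exon
models the simulator plants and adequate for split genes. aligned_fraction
counts only M-column query residues (gap-bridging insertions do not count
as coverage); similarity is the positive-scoring column fraction, the
closest well-defined analogue of an aligner-reported "similarity" whose
exact formula is not otherwise pinned down. Complete requires
aligned_fraction ≥ 95 and similarity > 90; any weaker alignment is
Partial; no alignment is Absent.

## Sex linkage

Calls use per-contig mean depths of a female and a male read set. The
autosomal baseline is the median over contigs that are not Z-homologous
(fraction ≤ 0.60) and pass a 10-kb length floor, so sex chromosomes cannot
contaminate their own baseline. With t = 0.25: Z is called for Z-homology
> 0.60 or (f-ratio within 0.5 ± t and m-ratio within 1 ± t); W for f-ratio
within 0.5 ± t and m-ratio < 0.1; PAR-or-autosome for both ratios within
1 ± t; anything else Unclassified. The half- and zero-coverage expectations
have no published numeric windows, so t and the W male ceiling are declared
defaults of this package, printed in every report header, and the calls are
scaling-invariant by construction. The Z-homology fraction is computed by
aligning the contig in 1-kb chunks (whole-contig quadratic DP would not
scale) and merging passing-hit query intervals; chunk hits are filtered on
identity and e-value but not on per-chunk coverage, which would erase
genuine homology in the chunk straddling the boundary. A scaffold is
chimeric when it contains at least one Z- or W-called contig and at least
one autosomal one; Unclassified members are ignored.

## The synthetic truth genome

The simulator emulates the architecture that makes bird genomes hard to
assemble; defaults are the study conditions the package is validated
against. Four 500-kb macrochromosomes (GC 42%), four 100-kb
microchromosomes (GC 60%), a 300-kb Z, a 150-kb W (GC 45%, repeat density
70%), and a 30-kb pseudoautosomal segment give a ~2.9-Mb genome. Planted
features: LTR retrotransposons (8 kb, 800-bp terminal repeats ≥ 99%
identical within an element, ~3% per-copy divergence from the family
consensus, plus internal-region fragments), LINEs (5 kb full length,
5'-truncated geometrically in kb chunks from the 3' end, p = 0.4, ~4%
divergence), satellite arrays (170-bp unit, 5–40 copies, per-copy
divergence uniform in [0, 2]% — low enough that collapse, not divergence,
drives assembly difficulty), simple repeats (2–6-bp motifs), DNA
transposons, and adjacent LTR-fragment/simple-repeat pairs that produce
Complex-cause gaps. A tandem cluster of 12 exon paralogs (90 codons, 2–8%
nucleotide divergence, mixed strands) sits on one microchromosome, plus one
copy truncated to exactly 80 codons with intact ends — its insertion-free
hit length is exactly 240 nt, the boundary the census must exclude. Six
single-exon genes are spread over the macrochromosomes. All exon cassettes
are flanked by in-frame stop codons so translated-hit boundaries are exact.
Repeat consensi and simple-repeat motifs are drawn G4-free (and without
GG/CC in tiled motifs), so the G4 signal tracks chromosome base composition
rather than which chromosome happened to receive repeat arrays.

Features are separated by at least 650 bp of unique background. This
spacing is load-bearing: whole-feature excisions take margins of 20–75 bp,
so every liftover flank of such a gap lies in unique sequence, and the
identity-liftover guarantee (every eligible gap scorable and exactly
projected) is achievable by construction rather than by luck. Draft
derivation samples ~200 breakable features (odds configurable per class)
plus ~12 background breaks; satellites and simple repeats are collapsed to
a 2-unit / 30-bp stub (leaving the adjacency signal a real assembler would
leave), LTR elements are deleted whole or split inside the internal region
(flanks stay clear of the near-identical terminal repeats), LINEs are
deleted or split. Excisions closer than 500 bp (one flank length) are
dropped so no flank ever contains another gap's Ns. Forced cases: a break
immediately after one copy of a planted 500-bp inter-chromosomal
duplication (its left flank *is* the duplicated segment → NotScorable
ambiguous), one gene split mid-length (→ Partial), one gene fully excised
(→ Absent), and one chimeric scaffold made by relocating the terminal
contig of the last macrochromosome onto the W scaffold (its junction gap →
NotScorable different_scaffolds, and the coverage classifier must flag the
scaffold). Per-base substitutions at `mutation_rate` apply to the draft
only. Coverage simulation draws Poisson(length × depth × ploidy)/length
per contig with ploidy 1 for autosomes/PAR in both sexes, 0.5/1.0
(female/male) for Z, and 0.5/0.0 for W.

Randomness is one RNG stream per (seed, stage name), so adding a stage
never perturbs earlier stages' draws and all outputs are byte-reproducible
from (config, seed).

What the simulator does *not* emulate — and what passing tests therefore do
not show about real data: sequencing errors and platform-specific error
profiles (mutation is substitution-only and uniform), indel polymorphism,
segmental duplications beyond the one planted pair, tandem duplications at
sub-window spacing, nested or fragmented repeat structures, translocations
or inversions between draft and reference (all contigs map forward-strand),
GC-dependent coverage bias, and spliced multi-exon genes. Results on real
assemblies additionally depend on the upstream repeat annotation and on the
reference being the same individual or a very close relative; at the
default 98% identity filter, flank alignment tolerates roughly 1%
divergence before scorability degrades (at 1% simulated mutation, ~3% of
gaps lose a flank to the identity filter and recovery settles around
96–97%).

## Problem sizes

The validation runs use the ~2.9-Mb default genome with ~215 gaps (about
45 s per full liftover analysis on one CPU), 200 random ≤ 2-kb pairs for
the aligner oracle, and ≥ 1,000 random instances per interval/statistic
oracle. `scripts/acceptance.py` performs two full synthetic runs
(mutation-free and 1% mutated) plus all secondary analyses in about two
minutes.
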