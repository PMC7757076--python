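"""Analysis configuration shared across the pipeline stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict


@dataclass
class ExonQuerySpec:
    """Name plus the length filters of one exon query set.

    ``query_alignment_length`` is the nucleotide span of the query alignment;
    ``min_hit_len`` is the strict lower bound on the insertion-free hit length
    (hits must be *longer than* this to count).
    """

    name: str
    query_alignment_length: int
    min_hit_len: int

    def __post_init__(self):
        if not self.min_hit_len < self.query_alignment_length:
            raise ValueError("min_hit_len must be below query_alignment_length")


@dataclass
class AnalysisConfig:
    """Thresholds for the gap, liftover, composition and homology analyses.

    Defaults follow the published analysis: 500-bp flanks, gaps > 10 bp,
    a 100-bp adjacency window, 98% identity / 90% coverage / 1e-20 e-value
    alignment filters, 1-kb GC windows at the 58.8% (alternatively 70%)
    threshold, the 95%-length / 90%-similarity complete-gene rule, and the
    60% Z-homology rule. ``contig_split_n`` (25) is the assemblathon-style
    scaffold-to-contig split threshold.
    """

    flank_len: int = 500
    min_gap_len_analysis: int = 11  # i.e. gaps > 10 bp
    adjacency_window: int = 100
    min_identity: float = 98.0
    min_flank_coverage: float = 90.0
    max_evalue: float = 1e-20
    gc_window: int = 1000
    gc_threshold: float = 58.8
    gc_threshold_alt: float = 70.0
    contig_split_n: int = 25
    exon_queries: list[ExonQuerySpec] = field(
        default_factory=lambda: [
            ExonQuerySpec("exon2", 270, 240),
            ExonQuerySpec("exon3", 220, 195),
        ]
    )
    complete_gene_min_len: float = 95.0
    complete_gene_min_sim: float = 90.0
    z_homology_min: float = 0.60
    max_projected_span: int = 100_000
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "flank_len",
            "adjacency_window",
            "min_identity",
            "min_flank_coverage",
            "max_evalue",
            "gc_window",
            "gc_threshold",
            "contig_split_n",
            "complete_gene_min_len",
            "complete_gene_min_sim",
            "z_homology_min",
            "max_projected_span",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.min_gap_len_analysis < 1:
            raise ValueError("min_gap_len_analysis must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "exon_queries" in d:
            d["exon_queries"] = [
                ExonQuerySpec(**q) if isinstance(q, dict) else ExonQuerySpec(*q)
                for q in d["exon_queries"]
            ]
        return cls(**d)
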