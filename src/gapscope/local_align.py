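"""Built-in seed-and-extend local aligner and six-frame translated search.

No external binaries: nucleotide liftover and protein censusing run on a
k-mer-seeded, window-restricted affine-gap Smith-Waterman. For small targets
the full dynamic program is run directly, so on desk-scale sequences the
reported best score *is* the Smith-Waterman optimum.

The row-wise DP is exact and vectorized: the horizontal (gap-in-query) state
E of an affine local alignment satisfies
``E[i][j] = max_{j'<j} Hpre[i][j'] - open - ext*(j-j')``
where ``Hpre`` is the cell value before considering E (0/diagonal/vertical),
because re-opening a horizontal gap from a cell whose value came from E is
always dominated by extending the existing gap. That max is a running prefix
maximum, so each DP row is a handful of numpy operations.

E-values use the Karlin-Altschul form ``K * m * n * exp(-lambda * S)`` with
constants fixed per scoring scheme (declared below, not fitted); they differ
numerically from BLAST's but agree within the order of magnitude that
matters against a 1e-20 cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .config import AnalysisConfig
from .genome_io import GenomeSequences, Interval

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# alphabets and scoring

_NT_ORDER = "ACGTN"
_NT_LOOKUP = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(_NT_ORDER):
    _NT_LOOKUP[ord(_c)] = _i

_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_LOOKUP = np.full(256, _AA_ORDER.index("X"), dtype=np.uint8)
for _i, _c in enumerate(_AA_ORDER):
    _AA_LOOKUP[ord(_c)] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def encode_nt(seq: str) -> np.ndarray:
    return _NT_LOOKUP[np.frombuffer(seq.encode(), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return _AA_LOOKUP[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _nt_matrix(match: int, mismatch: int) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.int32)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch  # N never matches, not even N
    m[:, 4] = mismatch
    return m


def _blosum62_matrix(stop_penalty: int = -1000) -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(_AA_ORDER)
    m = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(_AA_ORDER):
        for j, b in enumerate(_AA_ORDER):
            if a in "*X" or b in "*X":
                # alignments never cross stop codons or N-run translations,
                # so frames effectively break at stops and assembly gaps
                m[i, j] = stop_penalty
            else:
                m[i, j] = int(blosum[a][b])
    return m


@dataclass
class AlignParams:
    """Scoring, seeding, and statistics knobs for the local aligner.

    Nucleotide defaults: match +2 / mismatch -3, gap open 5 / extend 2 (a gap
    of length L costs open + L*ext), K=0.41, lambda=0.625. Seed length k=15,
    lowerable to 11 for diverged fixtures.
    """

    k: int = 15
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    karlin_k: float = 0.41
    karlin_lambda: float = 0.625
    min_score: int = 40
    max_full_dp: int = 5000  # targets up to this length get a full DP, no seeding
    min_cluster_seeds: int = 2
    cluster_join: int = 400  # max bp between consecutive seeds in one cluster
    window_pad_factor: float = 1.0  # window padding = factor * query length
    max_hits: int = 50


@dataclass
class ProteinParams(AlignParams):
    """Translated-search defaults: BLOSUM62, gap open 11 / extend 1,
    K=0.041, lambda=0.267 (gapped BLOSUM62 constants)."""

    k: int = 5
    gap_open: int = 11
    gap_extend: int = 1
    karlin_k: float = 0.041
    karlin_lambda: float = 0.267
    min_score: int = 45
    max_full_dp: int = 2000


@dataclass
class AlignmentHit:
    """One local alignment with identity/coverage/e-value and an edit trace.

    ``trace`` is CIGAR-like: a list of (op, length) with op 'M' (both),
    'I' (query only; insertion relative to the target), 'D' (target only).
    For translated hits the query span is in residues, the target span in
    nucleotides on the forward strand, and the trace is in residue columns.
    """

    query_name: str
    target_name: str
    query_span: Interval
    target_span: Interval
    strand: str
    matches: int
    mismatches: int
    gap_opens: int
    aligned_cols: int
    identity: float
    query_coverage: float
    raw_score: int
    evalue: float
    trace: list[tuple[str, int]] = field(default_factory=list)
    positives: int = 0
    translated: bool = False


# ---------------------------------------------------------------------------
# exact affine-gap local DP

def _sw_fill(q: np.ndarray, t: np.ndarray, sub: np.ndarray, go: int, ge: int):
    """Fill H/E/F matrices for local affine alignment of q (rows) vs t (cols)."""
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), np.iinfo(np.int32).min // 2, dtype=np.int32)
    F = np.full((n + 1, m + 1), np.iinfo(np.int32).min // 2, dtype=np.int32)
    jarange = np.arange(m + 1, dtype=np.int64) * ge
    for i in range(1, n + 1):
        F[i] = np.maximum(F[i - 1] - ge, H[i - 1] - go - ge)
        hpre = np.maximum(F[i][1:], H[i - 1][:-1] + sub[q[i - 1]][t])
        hpre = np.maximum(hpre, 0)
        hpre_full = np.concatenate(([0], hpre))
        pref = np.maximum.accumulate(hpre_full + jarange)
        E[i][1:] = pref[:-1] - go - jarange[1:]
        H[i] = np.maximum(hpre_full, E[i])
        H[i][0] = 0
    return H, E, F


def _sw_traceback(q, t, sub, go, ge, H, E, F):
    """Best local alignment endpoints, counts, and edit trace."""
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    score = int(H[i, j])
    if score <= 0:
        return None
    qe, te = i, j
    ops: list[str] = []
    matches = mismatches = gap_opens = positives = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = sub[q[i - 1], t[j - 1]]
            if h == H[i - 1, j - 1] + s:
                ops.append("M")
                if q[i - 1] == t[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                if s > 0:
                    positives += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            elif h == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback inconsistency")
        elif state == "E":  # gap in query, consume target
            # extension preferred over re-opening: always consistent with the
            # prefix-max E matrix (see module docstring)
            ops.append("D")
            if E[i, j] == E[i, j - 1] - ge:
                j -= 1
            else:
                j -= 1
                gap_opens += 1
                state = "H"
        else:  # state == "F": gap in target, consume query
            ops.append("I")
            if F[i, j] == F[i - 1, j] - ge:
                i -= 1
            else:
                i -= 1
                gap_opens += 1
                state = "H"
    qs, ts = i, j
    ops.reverse()
    trace: list[tuple[str, int]] = []
    for op in ops:
        if trace and trace[-1][0] == op:
            trace[-1] = (op, trace[-1][1] + 1)
        else:
            trace.append((op, 1))
    aligned_cols = matches + mismatches  # M columns only
    return {
        "score": score,
        "q_start": qs,
        "q_end": qe,
        "t_start": ts,
        "t_end": te,
        "matches": matches,
        "mismatches": mismatches,
        "gap_opens": gap_opens,
        "aligned_cols": aligned_cols,
        "positives": positives,
        "trace": trace,
    }


def smith_waterman(q: np.ndarray, t: np.ndarray, sub: np.ndarray, go: int, ge: int):
    """Full local affine-gap alignment; returns None if no positive score."""
    if len(q) == 0 or len(t) == 0:
        return None
    H, E, F = _sw_fill(q, t, sub, go, ge)
    return _sw_traceback(q, t, sub, go, ge, H, E, F)


def sw_score(q: np.ndarray, t: np.ndarray, sub: np.ndarray, go: int, ge: int) -> int:
    """Best local score only (no traceback)."""
    if len(q) == 0 or len(t) == 0:
        return 0
    H, _, _ = _sw_fill(q, t, sub, go, ge)
    return int(H.max())


# ---------------------------------------------------------------------------
# k-mer seeding

def _kmer_codes(arr: np.ndarray, k: int, alphabet: int, invalid_code: int):
    """Vectorized k-mer codes: (positions, codes) for windows free of codes
    >= invalid_code (N for nucleotides; X and * for protein)."""
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        codes = codes * alphabet + arr[j : j + n - k + 1]
    bad = arr >= invalid_code
    cnt = np.concatenate(([0], np.cumsum(bad)))
    valid = (cnt[k:] - cnt[:-k]) == 0
    return np.nonzero(valid)[0].astype(np.int64), codes[valid]


class KmerIndex:
    """Sorted-array exact k-mer index over one encoded sequence."""

    def __init__(self, arr: np.ndarray, k: int, alphabet: int, invalid_code: int):
        self.k = k
        pos, codes = _kmer_codes(arr, k, alphabet, invalid_code)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.codes, code, side="left")
        hi = np.searchsorted(self.codes, code, side="right")
        return self.pos[lo:hi]


def _query_kmers(arr: np.ndarray, k: int, alphabet: int, invalid_code: int):
    pos, codes = _kmer_codes(arr, k, alphabet, invalid_code)
    return list(zip(pos.tolist(), codes.tolist()))


def _seed_windows(seeds: list[tuple[int, int]], qlen: int, tlen: int, params: AlignParams):
    """Cluster (qpos, tpos) seeds into target windows for restricted DP.

    Seeds are clustered along the target; a new cluster starts when the gap
    to the previous seed exceeds ``cluster_join``. Windows are padded by the
    query length so optimal alignments can extend beyond the seeded core;
    overlapping windows are merged.
    """
    if not seeds:
        return []
    seeds = sorted(seeds, key=lambda s: s[1])
    clusters: list[list[tuple[int, int]]] = [[seeds[0]]]
    for s in seeds[1:]:
        if s[1] - clusters[-1][-1][1] <= params.cluster_join:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    pad = int(params.window_pad_factor * qlen) + params.k
    windows = []
    for cl in clusters:
        if len(cl) < params.min_cluster_seeds:
            continue
        t_lo = max(0, cl[0][1] - pad)
        t_hi = min(tlen, cl[-1][1] + params.k + pad)
        windows.append((t_lo, t_hi))
    windows.sort()
    merged = []
    for w in windows:
        if merged and w[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w[1]))
        else:
            merged.append(list(w))
    return [tuple(w) for w in merged]


# ---------------------------------------------------------------------------
# engines

class _Engine:
    """Seed-and-extend over a fixed set of encoded target sequences."""

    def __init__(self, targets: dict[str, np.ndarray], sub: np.ndarray, params: AlignParams,
                 alphabet: int, invalid_code: int):
        self.targets = targets
        self.sub = sub
        self.params = params
        self.alphabet = alphabet
        self.invalid_code = invalid_code
        self.total_len = sum(len(a) for a in targets.values())
        self._indices: dict[str, KmerIndex] = {}

    def _index(self, name: str) -> KmerIndex:
        if name not in self._indices:
            self._indices[name] = KmerIndex(
                self.targets[name], self.params.k, self.alphabet, self.invalid_code
            )
        return self._indices[name]

    def search(self, q: np.ndarray) -> list[dict]:
        """Raw alignments of q against every target (forward orientation)."""
        p = self.params
        results = []
        qk = None
        for name, tarr in self.targets.items():
            if len(tarr) <= p.max_full_dp:
                aln = smith_waterman(q, tarr, self.sub, p.gap_open, p.gap_extend)
                if aln and aln["score"] >= p.min_score:
                    aln["target"] = name
                    results.append(aln)
                continue
            if qk is None:
                qk = _query_kmers(q, p.k, self.alphabet, self.invalid_code)
            idx = self._index(name)
            seeds = []
            for qpos, code in qk:
                for tpos in idx.lookup(code):
                    seeds.append((qpos, int(tpos)))
            for t_lo, t_hi in _seed_windows(seeds, len(q), len(tarr), p):
                aln = smith_waterman(q, tarr[t_lo:t_hi], self.sub, p.gap_open, p.gap_extend)
                if aln and aln["score"] >= p.min_score:
                    aln["t_start"] += t_lo
                    aln["t_end"] += t_lo
                    aln["target"] = name
                    results.append(aln)
        return results


class NucleotideAligner:
    """Reusable nucleotide aligner over one target set (index built once)."""

    def __init__(self, targets: GenomeSequences, params: AlignParams | None = None):
        self.params = params or AlignParams()
        self.sub = _nt_matrix(self.params.match, self.params.mismatch)
        self._engine = _Engine(
            {name: encode_nt(seq) for name, seq in targets.items()},
            self.sub,
            self.params,
            alphabet=4,
            invalid_code=4,
        )
        self.target_names = targets.names()

    def _evalue(self, score: int, qlen: int) -> float:
        p = self.params
        x = p.karlin_lambda * score
        try:
            return p.karlin_k * qlen * self._engine.total_len * math.exp(-x)
        except OverflowError:  # pragma: no cover
            return 0.0

    def align(self, query: str, query_name: str = "query") -> list[AlignmentHit]:
        p = self.params
        if len(query) < p.k:
            log.warning("query %s shorter than seed length %d; no hits", query_name, p.k)
            return []
        qlen = len(query)
        hits: list[AlignmentHit] = []
        for strand, qseq in (("+", query), ("-", revcomp(query))):
            qarr = encode_nt(qseq)
            for aln in self._engine.search(qarr):
                if strand == "+":
                    q_s, q_e = aln["q_start"], aln["q_end"]
                else:
                    q_s, q_e = qlen - aln["q_end"], qlen - aln["q_start"]
                hits.append(
                    AlignmentHit(
                        query_name=query_name,
                        target_name=aln["target"],
                        query_span=Interval(query_name, q_s, q_e),
                        target_span=Interval(aln["target"], aln["t_start"], aln["t_end"], strand),
                        strand=strand,
                        matches=aln["matches"],
                        mismatches=aln["mismatches"],
                        gap_opens=aln["gap_opens"],
                        aligned_cols=aln["aligned_cols"],
                        identity=100.0 * aln["matches"] / aln["aligned_cols"],
                        query_coverage=100.0 * (q_e - q_s) / qlen,
                        raw_score=aln["score"],
                        evalue=self._evalue(aln["score"], qlen),
                        trace=aln["trace"],
                        positives=aln["positives"],
                    )
                )
        hits = _dedup_hits(hits)
        hits.sort(key=_hit_order)
        return hits[: p.max_hits]


def _hit_order(h: AlignmentHit):
    # ascending e-value; ties: lowest target coordinate, then '+' before '-'
    return (h.evalue, -h.raw_score, h.target_name, h.target_span.start, 0 if h.strand == "+" else 1)


def _dedup_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop the weaker of two hits overlapping on the same target and strand."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda x: -x.raw_score):
        clash = any(
            k.target_name == h.target_name
            and k.strand == h.strand
            and k.target_span.start < h.target_span.end
            and h.target_span.start < k.target_span.end
            for k in kept
        )
        if not clash:
            kept.append(h)
    return kept


def align_local(query: str, targets: GenomeSequences, params: AlignParams | None = None,
                query_name: str = "query") -> list[AlignmentHit]:
    """One-shot local nucleotide alignment (builds a fresh aligner).

    For repeated queries against the same target set, construct a
    :class:`NucleotideAligner` once and call ``align``.
    """
    return NucleotideAligner(targets, params).align(query, query_name)


def filter_hits(hits: list[AlignmentHit], cfg: AnalysisConfig) -> list[AlignmentHit]:
    """Keep hits with identity >= min_identity, coverage >= min_flank_coverage
    and e-value <= max_evalue (all boundaries inclusive); order preserved."""
    return [
        h
        for h in hits
        if h.identity >= cfg.min_identity
        and h.query_coverage >= cfg.min_flank_coverage
        and h.evalue <= cfg.max_evalue
    ]


# ---------------------------------------------------------------------------
# six-frame translated search

_AA_SET = set("ACDEFGHIKLMNPQRSTVWY")


class _Frame:
    def __init__(self, target: str, strand: str, offset: int, aa: str, target_len: int):
        self.target = target
        self.strand = strand
        self.offset = offset
        self.aa = aa
        self.target_len = target_len

    def nt_span(self, a_start: int, a_end: int) -> tuple[int, int]:
        """Forward-strand nt coordinates of residue range [a_start, a_end)."""
        if self.strand == "+":
            return self.offset + 3 * a_start, self.offset + 3 * a_end
        # residues count along the reverse complement
        hi = self.target_len - self.offset - 3 * a_start
        lo = self.target_len - self.offset - 3 * a_end
        return lo, hi


def six_frame_translations(seqs: GenomeSequences) -> list[_Frame]:
    frames: list[_Frame] = []
    for name, seq in seqs.items():
        L = len(seq)
        rc = revcomp(seq)
        for strand, s in (("+", seq), ("-", rc)):
            for f in range(3):
                usable = (L - f) // 3 * 3
                if usable < 3:
                    continue
                aa = str(Seq(s[f : f + usable]).translate())
                frames.append(_Frame(name, strand, f, aa, L))
    return frames


class TranslatedAligner:
    """Six-frame BLOSUM62 search of protein queries against a nucleotide
    target set; hit target spans are nucleotide coordinates, query spans are
    residue coordinates, strand comes from the frame sign. Stop codons carry
    a prohibitive score, so alignments never cross them (frames effectively
    break at stops)."""

    def __init__(self, targets: GenomeSequences, params: ProteinParams | None = None):
        self.params = params or ProteinParams()
        self.sub = _blosum62_matrix()
        self.frames = six_frame_translations(targets)
        enc = {str(i): encode_aa(fr.aa) for i, fr in enumerate(self.frames)}
        self._engine = _Engine(
            enc, self.sub, self.params,
            alphabet=len(_AA_ORDER),
            invalid_code=_AA_ORDER.index("X"),  # X and * excluded from seeds
        )

    def _evalue(self, score: int, qlen: int) -> float:
        p = self.params
        try:
            return p.karlin_k * qlen * self._engine.total_len * math.exp(-p.karlin_lambda * score)
        except OverflowError:  # pragma: no cover
            return 0.0

    def align(self, query: str, query_name: str = "query") -> list[AlignmentHit]:
        bad = set(query.upper()) - _AA_SET
        if bad:
            raise ValueError(f"non-amino-acid characters in query: {sorted(bad)}")
        if len(query) < 20:
            raise ValueError("protein query must be >= 20 residues")
        qarr = encode_aa(query.upper())
        qlen = len(query)
        hits: list[AlignmentHit] = []
        for aln in self._engine.search(qarr):
            fr = self.frames[int(aln["target"])]
            nt_lo, nt_hi = fr.nt_span(aln["t_start"], aln["t_end"])
            hits.append(
                AlignmentHit(
                    query_name=query_name,
                    target_name=fr.target,
                    query_span=Interval(query_name, aln["q_start"], aln["q_end"]),
                    target_span=Interval(fr.target, nt_lo, nt_hi, fr.strand),
                    strand=fr.strand,
                    matches=aln["matches"],
                    mismatches=aln["mismatches"],
                    gap_opens=aln["gap_opens"],
                    aligned_cols=aln["aligned_cols"],
                    identity=100.0 * aln["matches"] / aln["aligned_cols"],
                    query_coverage=100.0 * (aln["q_end"] - aln["q_start"]) / qlen,
                    raw_score=aln["score"],
                    evalue=self._evalue(aln["score"], qlen),
                    trace=aln["trace"],
                    positives=aln["positives"],
                    translated=True,
                )
            )
        hits = _dedup_hits(hits)
        hits.sort(key=_hit_order)
        return hits[: self.params.max_hits]


def translated_search(protein_query: str, targets: GenomeSequences,
                      params: ProteinParams | None = None,
                      query_name: str = "query") -> list[AlignmentHit]:
    """One-shot translated search; see :class:`TranslatedAligner` for reuse."""
    return TranslatedAligner(targets, params).align(protein_query, query_name)


# ---------------------------------------------------------------------------
# external tabular import (outfmt-6-like)

def read_tabular_hits(path, query_lengths: dict[str, int] | None = None) -> list[AlignmentHit]:
    """Map a 12-column tabular alignment file (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore; 1-based
    inclusive) into AlignmentHit; sstart > send encodes the '-' strand.

    Without ``query_lengths`` the query coverage cannot be computed and is
    set to NaN with a warning.
    """
    hits: list[AlignmentHit] = []
    warned = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            (qid, sid, pident, length, mism, gapo, qs, qe, ss, se, ev, bits) = line.split("\t")[:12]
            qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
            strand = "+" if ss <= se else "-"
            if strand == "-":
                ss, se = se, ss
            aligned = int(length)
            matches = round(aligned * float(pident) / 100.0)
            if query_lengths and qid in query_lengths:
                cov = 100.0 * (qe - qs + 1) / query_lengths[qid]
            else:
                if not warned:
                    log.warning("no query lengths supplied; query_coverage is NaN")
                    warned = True
                cov = float("nan")
            hits.append(
                AlignmentHit(
                    query_name=qid,
                    target_name=sid,
                    query_span=Interval(qid, qs - 1, qe),
                    target_span=Interval(sid, ss - 1, se, strand),
                    strand=strand,
                    matches=matches,
                    mismatches=int(mism),
                    gap_opens=int(gapo),
                    aligned_cols=aligned,
                    identity=float(pident),
                    query_coverage=cov,
                    raw_score=int(float(bits)),
                    evalue=float(ev),
                )
            )
    return hits
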