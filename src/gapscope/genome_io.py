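"""Data model, coordinate conventions, and readers/writers.

All internal coordinates are 0-based half-open. Conversions from external
conventions (RepeatMasker ``.out`` is 1-based inclusive; BED already matches)
happen only inside the readers and writers in this module, so the rest of the
pipeline never performs coordinate arithmetic across conventions.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

log = logging.getLogger(__name__)

#: Bases kept verbatim; every other IUPAC ambiguity code is folded to N.
_VALID = set("ACGTN")
_IUPAC_AMBIG = set("RYSWKMBDHVU")


class RepeatClass(Enum):
    """Canonical repeat groups used throughout the gap analyses.

    The enum order is the fixed tie-break order for adjacency classification.
    """

    LINE = "LINE"
    SINE = "SINE"
    LTR = "LTR"
    DNA = "DNA"
    Satellite = "Satellite"
    SimpleRepeat = "SimpleRepeat"
    LowComplexity = "LowComplexity"
    rRNA = "rRNA"
    Unknown = "Unknown"
    Other = "Other"


#: Mapping from RepeatMasker class/family strings to canonical classes.
#: Matching is by the text before the first '/', except for the exact
#: spellings RepeatMasker uses for simple/low-complexity rows. Editable:
#: readers accept a custom mapping with the same shape.
DEFAULT_CLASS_MAP: dict[str, RepeatClass] = {
    "LINE": RepeatClass.LINE,
    "SINE": RepeatClass.SINE,
    "LTR": RepeatClass.LTR,
    "DNA": RepeatClass.DNA,
    "RC": RepeatClass.Other,
    "Retroposon": RepeatClass.Other,
    "Satellite": RepeatClass.Satellite,
    "Simple_repeat": RepeatClass.SimpleRepeat,
    "Low_complexity": RepeatClass.LowComplexity,
    "rRNA": RepeatClass.rRNA,
    "tRNA": RepeatClass.Other,
    "snRNA": RepeatClass.Other,
    "scRNA": RepeatClass.Other,
    "srpRNA": RepeatClass.Other,
    "Unknown": RepeatClass.Unknown,
}


def classify_repeat_label(raw: str, class_map: dict[str, RepeatClass] | None = None) -> RepeatClass:
    """Map a RepeatMasker class/family string to a canonical RepeatClass."""
    table = DEFAULT_CLASS_MAP if class_map is None else class_map
    if raw in table:
        return table[raw]
    head = raw.split("/", 1)[0]
    if head in table:
        return table[head]
    # RepeatMasker sometimes suffixes with '?' for uncertain calls.
    head = head.rstrip("?")
    return table.get(head, RepeatClass.Unknown)


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, with optional strand."""

    seq_name: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.seq_name}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_name == other.seq_name and self.start < other.end and other.start < self.end

    def distance(self, other: "Interval") -> int:
        """Bases separating two intervals on the same sequence (0 if overlapping)."""
        if self.seq_name != other.seq_name:
            raise ValueError("distance across different sequences")
        return max(0, self.start - other.end, other.start - self.end)


class GenomeSequences:
    """Named scaffold sequences, uppercase over {A,C,G,T,N}.

    Keeps insertion order of the source file. ``folded_bases`` counts IUPAC
    ambiguity codes that were folded to N during normalization.
    """

    def __init__(self, records: dict[str, str], source_path: str = "", folded_bases: int = 0):
        self.records: dict[str, str] = records
        self.source_path = source_path
        self.folded_bases = folded_bases
        for name, seq in records.items():
            if not name:
                raise ValueError("empty sequence name")
            if not seq:
                raise ValueError(f"empty sequence for record {name}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def names(self) -> list[str]:
        return list(self.records)

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.records.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    def slice(self, iv: Interval) -> str:
        seq = self.records[iv.seq_name]
        if iv.end > len(seq):
            raise ValueError(f"interval {iv} exceeds sequence length {len(seq)}")
        return seq[iv.start : iv.end]

    def items(self):
        return self.records.items()


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase and fold IUPAC ambiguity codes (other than N) to N.

    Returns the normalized sequence and the number of folded bases.
    """
    seq = seq.upper()
    folded = 0
    if set(seq) - _VALID:
        out = []
        for c in seq:
            if c in _VALID:
                out.append(c)
            elif c in _IUPAC_AMBIG:
                out.append("N")
                folded += 1
            else:
                raise ValueError(f"invalid character {c!r} in sequence")
        seq = "".join(out)
    return seq, folded


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> GenomeSequences:
    """Read a (possibly gzipped) multi-record FASTA into GenomeSequences.

    Duplicate names and empty sequences are hard errors; ambiguity codes are
    folded to N with a logged count.
    """
    records: dict[str, str] = {}
    folded_total = 0
    name = None
    chunks: list[str] = []

    def _commit():
        nonlocal folded_total
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"empty sequence for record {name}")
        norm, folded = normalize_sequence(seq)
        folded_total += folded
        records[name] = norm

    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _commit()
                name = line[1:].split()[0]
                if name in records:
                    raise ValueError(f"duplicate name {name}")
                chunks = []
            else:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line)
        _commit()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if folded_total:
        log.warning("folded %d ambiguity bases to N while reading %s", folded_total, path)
    return GenomeSequences(records, source_path=str(path), folded_bases=folded_total)


def write_fasta(seqs: GenomeSequences, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class RepeatRecord:
    """One annotated repeat: an interval plus class/family metadata."""

    interval: Interval
    repeat_class: RepeatClass
    family_name: str = ""
    full_length: bool = False
    divergence: float | None = None


class RepeatAnnotation:
    """Strand-aware repeat intervals, sorted by (seq_name, start)."""

    def __init__(self, records: Iterable[RepeatRecord]):
        self.records: list[RepeatRecord] = sorted(
            records, key=lambda r: (r.interval.seq_name, r.interval.start, r.interval.end)
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RepeatRecord]:
        return iter(self.records)

    def by_class(self, cls: RepeatClass) -> list[RepeatRecord]:
        return [r for r in self.records if r.repeat_class is cls]

    def class_bp(self) -> dict[RepeatClass, int]:
        """Per-class bp totals after merging self-overlaps within class."""
        out: dict[RepeatClass, int] = {}
        for cls in RepeatClass:
            ivs = [r.interval for r in self.by_class(cls)]
            if ivs:
                out[cls] = intervals_bp(merge_intervals(ivs))
        return out

    def total_bp(self) -> int:
        return intervals_bp(merge_intervals([r.interval for r in self.records]))


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals per sequence; strictly overlapping OR abutting runs
    are merged (this is the plain genomic union used for bp totals)."""
    by_seq: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_name, []).append(iv)
    merged: list[Interval] = []
    for seq in sorted(by_seq):
        ivs = sorted(by_seq[seq], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(Interval(seq, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(Interval(seq, cur_s, cur_e))
    return merged


def intervals_bp(intervals: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in intervals)


def read_repeatmasker_out(
    path,
    assembly: GenomeSequences | None = None,
    class_map: dict[str, RepeatClass] | None = None,
) -> RepeatAnnotation:
    """Parse a RepeatMasker ``.out`` table (3 header lines, whitespace columns).

    1-based inclusive coordinates become 0-based half-open; strand code 'C'
    becomes '-'. Rows naming sequences absent from ``assembly`` (when given)
    are rejected with a counted warning. Malformed rows are skipped with a
    warning; more than 10% malformed is a hard error.
    """
    records: list[RepeatRecord] = []
    malformed = 0
    rejected = 0
    total = 0
    with _open_maybe_gzip(path) as fh:
        lines = fh.readlines()
    body = lines[3:] if len(lines) >= 3 and not lines[0].strip()[:1].isdigit() else lines
    for line in body:
        if not line.strip():
            continue
        total += 1
        parts = line.split()
        try:
            seq_name = parts[4]
            begin, end = int(parts[5]), int(parts[6])
            strand = "-" if parts[8] == "C" else "+"
            family = parts[9]
            raw_class = parts[10]
            divergence = float(parts[1])
            if begin < 1 or end < begin:
                raise ValueError("bad coordinates")
        except (IndexError, ValueError):
            malformed += 1
            log.warning("skipping malformed RepeatMasker row: %s", line.rstrip())
            continue
        if assembly is not None and seq_name not in assembly:
            rejected += 1
            continue
        records.append(
            RepeatRecord(
                interval=Interval(seq_name, begin - 1, end, strand),
                repeat_class=classify_repeat_label(raw_class, class_map),
                family_name=family,
                divergence=divergence,
            )
        )
    if total and malformed / total > 0.10:
        raise ValueError(f"{malformed}/{total} malformed rows in {path}")
    if rejected:
        log.warning("%d rows named sequences absent from the assembly", rejected)
    return RepeatAnnotation(records)


def write_bed(
    intervals: Iterable[tuple[Interval, str]],
    path,
    provenance: str | None = None,
) -> None:
    """Write labelled intervals as BED6 (name column = label, score 0)."""
    rows = list(intervals)
    for iv, _label in rows:  # validate before writing anything
        if iv.end <= iv.start:
            raise ValueError(f"invalid interval {iv}")
    with open(path, "w") as fh:
        if provenance:
            for pline in provenance.splitlines():
                fh.write(f"# {pline}\n")
        for iv, label in rows:
            strand = iv.strand if iv.strand in ("+", "-") else "+"
            fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{label}\t0\t{strand}\n")


def read_bed(path) -> list[tuple[Interval, str]]:
    """Read BED back into (Interval, label) pairs; '#' comment lines skipped."""
    out: list[tuple[Interval, str]] = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            seq, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            out.append((Interval(seq, start, end, strand), label))
    return out
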